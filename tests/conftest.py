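import numpy as np
import pytest

from windlodge.trial_data import LodgingDistribution


def make_distribution(bins, censored=0.0, s_max=30.0, cultivar="X", year=2016):
    """Convenience builder; ``bins`` is {speed: mass}."""
    return LodgingDistribution(
        cultivar=cultivar,
        year=year,
        bins=tuple(sorted(bins.items())),
        censored_mass=censored,
        s_max=s_max,
    )


def random_distribution(rng: np.random.Generator, s_max=30.0, max_bins=8):
    """A random valid lodging distribution on the default speed range."""
    n_bins = int(rng.integers(0, max_bins + 1))
    speeds = np.sort(rng.choice(np.arange(1, int(s_max) + 1), size=n_bins, replace=False))
    raw = rng.random(n_bins + 1)  # last entry is the censored mass
    if n_bins > 0 and rng.random() < 0.3:
        raw[-1] = 0.0
    masses = raw / raw.sum()
    return make_distribution(
        dict(zip(speeds.astype(float), masses[:-1])), censored=float(masses[-1]), s_max=s_max
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20160909)


@pytest.fixture
def table2_demo():
    """Hand-written two-year lodging counts whose FWS/CLI are hand-derivable.

    Cultivar ``A``: 60% of plants lodge at 12, 40% at 24 in year one
    (FWS 12, CLI 0.75); all 50 lodge at 20 in year two (FWS 20,
    CLI (20 + 10*0.5)/30 = 5/6). Cultivar ``B`` never lodges in either year
    (FWS censored > 30, CLI 1).
    """
    rows = [
        ("A", 2016, "12", 30), ("A", 2016, "24", 20), ("A", 2016, ">Smax", 0),
        ("B", 2016, ">Smax", 50),
        ("A", 2017, "20", 50),
        ("B", 2017, ">Smax", 50),
    ]
    return rows


def write_lodging_rows(path, rows):
    lines = ["cultivar,year,level_speed,lodged_count"]
    lines += [f"{c},{y},{s},{n}" for c, y, s, n in rows]
    path.write_text("\n".join(lines) + "\n")
    return path
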