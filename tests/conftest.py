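import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dualreporter import flow as fl
from dualreporter import synth

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def control_sample() -> fl.FlowSample:
    """A 100k-event non-fluorescent control, shared across flow tests."""
    return synth.make_control(n=100_000, seed=11)


@pytest.fixture(scope="session")
def gates(control_sample) -> fl.GateSet:
    return fl.fit_gates(control_sample, quantile=0.999)


@pytest.fixture(scope="session")
def ring_colony() -> synth.SyntheticColony:
    """A colony with a ring of expression at 50% radius plus a uniform channel."""
    return synth.make_colony(synth.ColonySpec(
        shape=(384, 384), radius=120.0,
        channels={"ring": synth.Ring(center=50.0, width=5.0),
                  "flat": synth.Uniform(level=8000.0)},
        seed=21,
    ))


def brute_force_pairs(genes):
    """Independent nested-loop enumeration of unordered gene pairs."""
    out = []
    genes = sorted(genes)
    for i in range(len(genes)):
        for j in range(len(genes)):
            if i < j:
                out.append((genes[i], genes[j]))
    return out


def brute_force_profile(channel: np.ndarray, percent: np.ndarray,
                        bin_resolution: float, max_percent: float):
    """Independent per-pixel group-by: dict of bin -> list of intensities."""
    groups: dict[float, list[float]] = {}
    flat_p = percent.ravel()
    flat_c = np.asarray(channel, dtype=float).ravel()
    for p, c in zip(flat_p, flat_c):
        b = round(p / bin_resolution) * bin_resolution
        if b <= max_percent:
            groups.setdefault(b, []).append(c)
    bins = sorted(groups)
    return (np.array(bins),
            np.array([len(groups[b]) for b in bins]),
            np.array([float(np.mean(groups[b])) for b in bins]))


def brute_force_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Covariance over product-of-sds, written out longhand."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).sum()
    sx = np.sqrt(((x - mx) ** 2).sum())
    sy = np.sqrt(((y - my) ** 2).sum())
    return cov / (sx * sy)
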