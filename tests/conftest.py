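import numpy as np
import pytest

from methylscape.segmentation import segment_sample
from methylscape.synthetic import CohortConfig, simulate_methylome_cohort
from methylscape.types import MethylomeSample


@pytest.fixture(scope="session")
def recovery_cohort():
    """Default-scale cohort (3 RA + 3 OA, 1e5 CpGs, 22x) with ground truth."""
    cfg = CohortConfig(rng_seed=1)
    samples, truth = simulate_methylome_cohort(cfg)
    return cfg, samples, truth


@pytest.fixture(scope="session")
def segmented_cohort(recovery_cohort):
    """Per-sample segmentation of the recovery cohort (PMDs + UMRs/LMRs)."""
    _, samples, truth = recovery_cohort
    segments = {}
    for s in samples:
        segs, _ = segment_sample(s, seed=1)
        segments[s.sample_id] = segs
    return samples, truth, segments


def make_sample(
    betas: np.ndarray,
    sample_id: str = "S",
    group: str = "RA",
    cov: int = 30,
    spacing: int = 100,
    seed: int | None = None,
    chrom: str = "chrS",
) -> MethylomeSample:
    """Build a sample from per-CpG methylation levels.

    With ``seed`` None, methylated counts are the rounded expectation
    (deterministic); otherwise they are binomial draws.
    """
    betas = np.asarray(betas, dtype=float)
    n = len(betas)
    covs = np.full(n, cov, dtype=np.int64)
    if seed is None:
        meth = np.rint(betas * cov).astype(np.int64)
    else:
        meth = np.random.default_rng(seed).binomial(covs, betas)
    return MethylomeSample(
        sample_id,
        group,
        np.full(n, chrom, dtype=object),
        np.arange(n, dtype=np.int64) * spacing + 500,
        covs,
        meth,
    )
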