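import numpy as np
import pytest

from cnclonal import (
    GenomeModel,
    GenomicInterval,
    Segment,
    SegmentedProfile,
    SimulationConfig,
    simulate_patient,
)


@pytest.fixture
def small_genome() -> GenomeModel:
    return GenomeModel(("1", "2"), (1000, 800))


@pytest.fixture
def toy_genome() -> GenomeModel:
    return GenomeModel.toy()


def make_profile(genome, sample_id, rows):
    """rows: iterable of (chrom, start, end, log_ratio[, marker_count])."""
    segs = []
    for row in rows:
        chrom, start, end, lr = row[:4]
        nmark = row[4] if len(row) > 4 else None
        segs.append(Segment(GenomicInterval(chrom, start, end), lr, nmark))
    return SegmentedProfile(sample_id, genome, tuple(segs))


@pytest.fixture
def make_profile_fn():
    return make_profile


def simulated_pair(seed, **config_kwargs):
    """One simulated patient's (primary, metastasis) observed profiles."""
    cfg = SimulationConfig(seed=seed, **config_kwargs)
    patient = simulate_patient(cfg, seed, patient_id=f"S{seed}")
    profiles = list(patient.profiles.values())
    return profiles[0], profiles[1]


def random_segmentation(rng, genome, sample_id="s", ndigits=6, coverage=1.0):
    """A random valid profile: random breakpoints, 6-dp log ratios.

    ``coverage < 1`` drops a random subset of segments (keeping >= 1).
    """
    segs = []
    for chrom, length in zip(genome.names, genome.lengths):
        n_bp = int(rng.integers(0, 5))
        cuts = np.unique(rng.integers(1, length, size=n_bp))
        bounds = np.concatenate([[0], cuts, [length]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            lr = round(float(rng.normal(0, 0.4)), ndigits)
            segs.append(Segment(GenomicInterval(chrom, int(lo), int(hi)), lr))
    if coverage < 1.0 and len(segs) > 1:
        keep = rng.random(len(segs)) < coverage
        if not keep.any():
            keep[int(rng.integers(len(segs)))] = True
        segs = [s for s, k in zip(segs, keep) if k]
    return SegmentedProfile(sample_id, genome, tuple(segs))
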