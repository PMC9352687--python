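"""Forward simulation of clonal tumors and their segmented log2 profiles.

Clones are integer copy-number profiles on a fixed breakpoint lattice
(100 kb by default).  A tumor sample is a mixture of clones diluted by
diploid normal cells at a given purity; the observed segmented log2 ratio
of a segment with mixture copy number q in a tumor of mean ploidy tau* is

    log2( (alpha*q + 2*(1-alpha)) / (alpha*tau* + 2*(1-alpha)) ) + noise

with Gaussian segment-level noise.  Two metastatic seeding modes are
modeled: ``polyclonal`` (the metastasis carries the primary's clone mixture
with mildly perturbed fractions) and ``monoclonal`` (the metastasis is a
single subclone).

All stochastic operations take explicit seeds or generators; cohort
generation derives per-patient seeds as ``master_seed + patient_index`` so
runs are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import (
    GenomeModel,
    GenomicInterval,
    Segment,
    SegmentedProfile,
    write_seg,
)

MODES = ("polyclonal", "monoclonal")

#: Relative copy number floor used before taking log2 (guards q == 0 at purity 1).
MIN_RELATIVE_CN = 2.0 ** -20


@dataclass(frozen=True)
class CNAEvent:
    """A copy-number event: +/- delta over an interval (may span a chromosome)."""

    interval: GenomicInterval
    delta: int
    whole_chromosome: bool = False

    def __post_init__(self) -> None:
        if self.delta == 0:
            raise ValueError("event delta must be non-zero")


@dataclass(frozen=True)
class CloneProfile:
    """Integer copy numbers per lattice bin, concatenated over chromosomes."""

    genome: GenomeModel
    bin_size: int
    copy: np.ndarray

    def __post_init__(self) -> None:
        for name, length in zip(self.genome.names, self.genome.lengths):
            if length % self.bin_size != 0:
                raise ValueError(
                    f"chromosome {name} length {length} is not a multiple of the "
                    f"{self.bin_size} bp lattice"
                )
        expected = self.genome.total_length // self.bin_size
        if len(self.copy) != expected:
            raise ValueError(f"expected {expected} bins, got {len(self.copy)}")
        if np.any(self.copy < 0):
            raise ValueError("copy numbers must be >= 0")

    @property
    def bins_per_chromosome(self) -> tuple[int, ...]:
        return tuple(length // self.bin_size for length in self.genome.lengths)

    @property
    def chromosome_offsets(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum(self.bins_per_chromosome)])

    @property
    def mean_copy_number(self) -> float:
        return float(self.copy.mean())


@dataclass(frozen=True)
class ClonalMixture:
    """Clones on a shared lattice with positive fractions summing to 1."""

    clones: tuple[CloneProfile, ...]
    fractions: np.ndarray

    def __post_init__(self) -> None:
        if len(self.clones) == 0:
            raise ValueError("mixture needs at least one clone")
        fr = np.asarray(self.fractions, dtype=float)
        if len(fr) != len(self.clones):
            raise ValueError("one fraction per clone required")
        if np.any(fr <= 0):
            raise ValueError("fractions must be positive")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {fr.sum()}")
        ref = self.clones[0]
        for clone in self.clones[1:]:
            if clone.genome != ref.genome or clone.bin_size != ref.bin_size:
                raise ValueError("clones must share genome and lattice")
        object.__setattr__(self, "fractions", fr)

    @property
    def genome(self) -> GenomeModel:
        return self.clones[0].genome


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 22
    chromosome_length: int = 10_000_000
    breakpoint_lattice: int = 100_000
    n_ancestral_events: int = 5
    n_subclones: int = 3
    n_events_per_subclone: int = 5
    purity_min: float = 0.4
    purity_max: float = 0.9
    noise_sd: float = 0.05
    seeding_mode: str = "polyclonal"
    n_primary: int = 1
    n_metastasis: int = 1
    whole_chromosome_prob: float = 0.3

    def __post_init__(self) -> None:
        if self.n_subclones < 1 or self.n_primary < 1 or self.n_metastasis < 1:
            raise ValueError("counts must be >= 1")
        if self.n_ancestral_events < 0 or self.n_events_per_subclone < 0:
            raise ValueError("event counts must be >= 0")
        if not (0.2 <= self.purity_min <= self.purity_max <= 1.0):
            raise ValueError("purity range must satisfy 0.2 <= min <= max <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.seeding_mode not in MODES:
            raise ValueError(f"seeding mode must be one of {MODES}")
        if self.chromosome_length % self.breakpoint_lattice != 0:
            raise ValueError("chromosome length must be a multiple of the lattice")

    @property
    def genome(self) -> GenomeModel:
        return GenomeModel.toy(self.n_chromosomes, self.chromosome_length)


@dataclass(frozen=True)
class SimulatedPatient:
    patient_id: str
    mode: str
    primary_truth: ClonalMixture
    metastasis_truth: ClonalMixture
    true_params: dict  # sample_id -> (purity, tumor ploidy)
    profiles: dict  # sample_id -> SegmentedProfile
    roles: dict  # sample_id -> "primary" | "metastasis"


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _apply_random_event(
    copy: np.ndarray,
    genome: GenomeModel,
    bins_per_chrom: Sequence[int],
    offsets: np.ndarray,
    bin_size: int,
    whole_chromosome_prob: float,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> CNAEvent:
    """Draw one event, resampling (bounded) if it would push a bin below 0."""
    n_chrom = len(bins_per_chrom)
    for _ in range(max_retries):
        chrom_i = int(rng.integers(n_chrom))
        delta = int(rng.choice(np.array([-1, 1, 2])))
        whole = bool(rng.random() < whole_chromosome_prob)
        nb = bins_per_chrom[chrom_i]
        if whole:
            b0, b1 = 0, nb
        else:
            pts = rng.choice(nb + 1, size=2, replace=False)
            b0, b1 = int(pts.min()), int(pts.max())
        lo, hi = offsets[chrom_i] + b0, offsets[chrom_i] + b1
        if np.min(copy[lo:hi]) + delta < 0:
            continue
        copy[lo:hi] += delta
        interval = GenomicInterval(genome.names[chrom_i], b0 * bin_size, b1 * bin_size)
        return CNAEvent(interval, delta, whole)
    raise RuntimeError("could not place a copy-number event without going below 0")


def simulate_clones(
    config: SimulationConfig, seed
) -> tuple[CloneProfile, tuple[CloneProfile, ...]]:
    """Generate an ancestor clone and its subclones.

    The ancestor is a diploid genome modified by ``n_ancestral_events``
    random events; each subclone adds ``n_events_per_subclone`` further
    events on top of the ancestor.
    """
    rng = _as_rng(seed)
    genome = config.genome
    bin_size = config.breakpoint_lattice
    bins_per_chrom = [length // bin_size for length in genome.lengths]
    offsets = np.concatenate([[0], np.cumsum(bins_per_chrom)])
    total_bins = int(offsets[-1])

    ancestor_copy = np.full(total_bins, 2, dtype=np.int64)
    for _ in range(config.n_ancestral_events):
        _apply_random_event(
            ancestor_copy, genome, bins_per_chrom, offsets, bin_size,
            config.whole_chromosome_prob, rng,
        )
    ancestor = CloneProfile(genome, bin_size, ancestor_copy.copy())

    subclones = []
    for _ in range(config.n_subclones):
        sub_copy = ancestor_copy.copy()
        for _ in range(config.n_events_per_subclone):
            _apply_random_event(
                sub_copy, genome, bins_per_chrom, offsets, bin_size,
                config.whole_chromosome_prob, rng,
            )
        subclones.append(CloneProfile(genome, bin_size, sub_copy))
    return ancestor, tuple(subclones)


def _joint_runs(mixture: ClonalMixture) -> tuple[list[GenomicInterval], np.ndarray]:
    """Maximal runs over which every clone is constant, per chromosome."""
    mat = np.vstack([clone.copy for clone in mixture.clones])
    ref = mixture.clones[0]
    bin_size = ref.bin_size
    offsets = ref.chromosome_offsets
    intervals: list[GenomicInterval] = []
    slices: list[tuple[int, int]] = []
    for ci, chrom in enumerate(ref.genome.names):
        lo, hi = int(offsets[ci]), int(offsets[ci + 1])
        block = mat[:, lo:hi]
        change = np.any(block[:, 1:] != block[:, :-1], axis=0)
        starts = np.concatenate([[0], np.flatnonzero(change) + 1])
        ends = np.concatenate([starts[1:], [hi - lo]])
        for s, e in zip(starts, ends):
            intervals.append(GenomicInterval(chrom, int(s) * bin_size, int(e) * bin_size))
            slices.append((lo + int(s), lo + int(e)))
    idx = np.array([s for s, _ in slices])
    values = (mixture.fractions @ mat)[idx]
    return intervals, values


def expected_segment_cn(
    mixture: ClonalMixture,
) -> tuple[tuple[GenomicInterval, ...], np.ndarray]:
    """Fraction-weighted mean copy number per joint segment of the mixture."""
    intervals, values = _joint_runs(mixture)
    return tuple(intervals), values


def tumor_ploidy(mixture: ClonalMixture) -> float:
    """Length-weighted mean copy number of the mixture (tau*)."""
    per_bin = mixture.fractions @ np.vstack([c.copy for c in mixture.clones])
    return float(per_bin.mean())


def observe_profile(
    mixture: ClonalMixture,
    purity: float,
    noise_sd: float,
    seed,
    *,
    sample_id: str = "sample",
) -> SegmentedProfile:
    """Observe a mixture as a segmented log2-ratio profile.

    With zero noise the length-weighted mean relative copy number of the
    output is exactly 1 (up to floating point).
    """
    if not 0.2 <= purity <= 1.0:
        raise ValueError(f"purity must be in [0.2, 1], got {purity}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _as_rng(seed)
    intervals, q = _joint_runs(mixture)
    tau = tumor_ploidy(mixture)
    normal = 2.0 * (1.0 - purity)
    r = (purity * q + normal) / (purity * tau + normal)
    r = np.maximum(r, MIN_RELATIVE_CN)
    log_ratio = np.log2(r)
    if noise_sd > 0:
        log_ratio = log_ratio + rng.normal(0.0, noise_sd, size=len(log_ratio))
    bin_size = mixture.clones[0].bin_size
    segments = tuple(
        Segment(iv, float(lr), marker_count=iv.length // bin_size)
        for iv, lr in zip(intervals, log_ratio)
    )
    return SegmentedProfile(sample_id, mixture.genome, segments)


def simulate_patient(
    config: SimulationConfig, seed, *, patient_id: str = "PT"
) -> SimulatedPatient:
    """Simulate one patient: clone structure, truth mixtures and observations."""
    rng = _as_rng(seed)
    ancestor, subclones = simulate_clones(config, rng)
    clones = (ancestor,) + subclones
    fractions = rng.dirichlet(np.ones(len(clones)))
    primary = ClonalMixture(clones, fractions)

    if config.seeding_mode == "polyclonal":
        met_fractions = rng.dirichlet(50.0 * fractions)
        metastasis = ClonalMixture(clones, met_fractions)
    else:
        pick = int(rng.integers(len(subclones)))
        metastasis = ClonalMixture((subclones[pick],), np.array([1.0]))

    profiles: dict[str, SegmentedProfile] = {}
    true_params: dict[str, tuple[float, float]] = {}
    roles: dict[str, str] = {}
    for mixture, role, count, tag in (
        (primary, "primary", config.n_primary, "P"),
        (metastasis, "metastasis", config.n_metastasis, "M"),
    ):
        tau = tumor_ploidy(mixture)
        for i in range(count):
            purity = float(rng.uniform(config.purity_min, config.purity_max))
            sid = f"{patient_id}_{tag}{i + 1}"
            profiles[sid] = observe_profile(
                mixture, purity, config.noise_sd, rng, sample_id=sid
            )
            true_params[sid] = (purity, tau)
            roles[sid] = role
    return SimulatedPatient(
        patient_id, config.seeding_mode, primary, metastasis, true_params, profiles, roles
    )


def simulate_cohort_tables(
    config: SimulationConfig, n_patients_per_mode: int, seed: int
) -> tuple[dict[str, SegmentedProfile], pd.DataFrame, pd.DataFrame]:
    """Simulate both seeding modes; return profiles, sample sheet and truth.

    Per-patient seeds are ``seed + patient_index`` with patients enumerated
    polyclonal first, so cohorts are reproducible and patients independent.
    """
    if n_patients_per_mode < 1:
        raise ValueError("n_patients_per_mode must be >= 1")
    profiles: dict[str, SegmentedProfile] = {}
    sheet_rows = []
    truth_rows = []
    index = 0
    for mode in MODES:
        mode_cfg = replace(config, seeding_mode=mode)
        for i in range(n_patients_per_mode):
            pid = f"{mode[:4]}{i + 1:03d}"
            patient = simulate_patient(mode_cfg, seed + index, patient_id=pid)
            index += 1
            for sid, profile in patient.profiles.items():
                profiles[sid] = profile
                sheet_rows.append(
                    {"sample_id": sid, "patient_id": pid,
                     "role": patient.roles[sid], "group": mode}
                )
                purity, tau = patient.true_params[sid]
                truth_rows.append(
                    {"sample_id": sid, "true_purity": purity,
                     "true_ploidy": tau, "mode": mode}
                )
    return profiles, pd.DataFrame(sheet_rows), pd.DataFrame(truth_rows)


def simulate_cohort(
    config: SimulationConfig,
    n_patients_per_mode: int,
    seed: int,
    out_dir: str | Path,
) -> tuple[Path, Path, Path]:
    """Simulate a cohort and write SEG, sample sheet and truth files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profiles, sheet, truth = simulate_cohort_tables(config, n_patients_per_mode, seed)
    seg_path = write_seg(profiles, out / "cohort.seg")
    sheet_path = out / "samples.tsv"
    sheet.to_csv(sheet_path, sep="\t", index=False, lineterminator="\n")
    truth_path = out / "truth.tsv"
    truth.to_csv(
        truth_path, sep="\t", index=False, float_format="%.6f", lineterminator="\n"
    )
    return seg_path, sheet_path, truth_path


def nudge_clone_to_grid_ploidy(clone: CloneProfile, step: float = 0.01) -> CloneProfile:
    """Adjust a clone minimally so its mean copy number lies on a ploidy lattice.

    Adds +1 to the fewest leading bins needed to make the bin-sum divisible
    by ``round(n_bins * step)``; used to build parameter-recovery fixtures
    whose true ploidy sits exactly on the search grid.
    """
    n = len(clone.copy)
    k = int(round(n * step))
    if k <= 0 or abs(n * step - k) > 1e-9:
        raise ValueError(f"{step} is not an exact ploidy step for {n} bins")
    rem = int(clone.copy.sum()) % k
    if rem == 0:
        return clone
    copy = clone.copy.copy()
    copy[: k - rem] += 1
    return CloneProfile(clone.genome, clone.bin_size, copy)
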