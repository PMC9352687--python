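"""End-to-end cohort analysis: orchestration, frequency tracks, group stats.

Outputs are tab-delimited tables with 6-decimal fixed-point reals; runs are
deterministic given the configuration and seed (the run log, which records
timings, is the only non-deterministic artifact).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from .cnh import SearchGrid, cnh_minimize
from .distance import cohort_distances
from .profiles import (
    GenomeModel,
    GenomicInterval,
    SegmentedProfile,
    infer_genome_from_seg,
    read_seg,
    restrict_to_autosomes,
)
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger("cnclonal")


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; the message names the stage."""


@dataclass(frozen=True)
class FrequencyTrack:
    """Per-bin fractions of samples with a copy-number gain or loss."""

    intervals: tuple[GenomicInterval, ...]
    n_samples: np.ndarray
    gain_fraction: np.ndarray
    loss_fraction: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.intervals)
        if n == 0:
            raise ValueError("frequency track has no bins")
        for arr in (self.n_samples, self.gain_fraction, self.loss_fraction):
            if len(arr) != n:
                raise ValueError("array lengths must match the bin count")
        if np.any(self.gain_fraction < 0) or np.any(self.gain_fraction > 1):
            raise ValueError("gain fractions must lie in [0, 1]")
        if np.any(self.loss_fraction < 0) or np.any(self.loss_fraction > 1):
            raise ValueError("loss fractions must lie in [0, 1]")
        if np.any(self.gain_fraction + self.loss_fraction > 1 + 1e-12):
            raise ValueError("gain + loss fraction exceeds 1 in some bin")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chromosome for iv in self.intervals],
                "start": [iv.start + 1 for iv in self.intervals],  # 1-based inclusive
                "end": [iv.end for iv in self.intervals],
                "n": self.n_samples.astype(int),
                "gain_frac": self.gain_fraction,
                "loss_frac": self.loss_fraction,
            }
        )


@dataclass(frozen=True)
class GroupComparison:
    groups: tuple[str, ...]
    summary: pd.DataFrame  # group, n, mean, median
    f_stat: float
    p_omnibus: float
    pairwise: pd.DataFrame  # group_a, group_b, mean_diff, p_adj, method

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_omnibus <= 1.0:
            raise ValueError("omnibus p-value out of [0, 1]")
        k = len(self.groups)
        if len(self.pairwise) != k * (k - 1) // 2:
            raise ValueError("pairwise table must have k*(k-1)/2 rows")


def aberration_frequency(
    profiles: Iterable[SegmentedProfile],
    gain_threshold: float = 0.1,
    loss_threshold: float = -0.1,
    bin_size: int = 1_000_000,
) -> FrequencyTrack:
    """Fraction of samples with log2 ratio above/below thresholds per bin.

    The genome is tiled into ``bin_size`` bins; a sample covers a bin if one
    of its segments contains the bin midpoint.  Samples not covering a bin
    are excluded from that bin's denominator; bins covered by no sample are
    dropped.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("at least one profile is required")
    if not gain_threshold > 0 > loss_threshold:
        raise ValueError("thresholds must satisfy gain > 0 > loss")
    genome = profiles[0].genome
    for p in profiles[1:]:
        if p.genome != genome:
            raise ValueError("profiles use different genome models")

    intervals: list[GenomicInterval] = []
    n_cov: list[int] = []
    gain: list[float] = []
    loss: list[float] = []
    by_chrom = []
    for p in profiles:
        chrom_map: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in genome.names:
            segs = [s for s in p.segments if s.interval.chromosome == chrom]
            if segs:
                chrom_map[chrom] = (
                    np.array([s.interval.start for s in segs]),
                    np.array([s.interval.end for s in segs]),
                    np.array([s.log_ratio for s in segs]),
                )
        by_chrom.append(chrom_map)

    for chrom, length in zip(genome.names, genome.lengths):
        n_bins = (length + bin_size - 1) // bin_size
        starts = np.arange(n_bins) * bin_size
        ends = np.minimum(starts + bin_size, length)
        mids = (starts + ends) // 2
        cov = np.zeros(n_bins, dtype=int)
        g = np.zeros(n_bins, dtype=int)
        lo = np.zeros(n_bins, dtype=int)
        for chrom_map in by_chrom:
            if chrom not in chrom_map:
                continue
            seg_starts, seg_ends, seg_vals = chrom_map[chrom]
            pos = np.searchsorted(seg_ends, mids, side="right")
            inside = (pos < len(seg_starts)) & (
                seg_starts[np.minimum(pos, len(seg_starts) - 1)] <= mids
            )
            vals = seg_vals[np.minimum(pos, len(seg_vals) - 1)]
            cov += inside
            g += inside & (vals > gain_threshold)
            lo += inside & (vals < loss_threshold)
        keep = cov > 0
        for i in np.flatnonzero(keep):
            intervals.append(GenomicInterval(chrom, int(starts[i]), int(ends[i])))
            n_cov.append(int(cov[i]))
            gain.append(g[i] / cov[i])
            loss.append(lo[i] / cov[i])
    if not intervals:
        raise ValueError("no profile covers any genome bin")
    return FrequencyTrack(
        tuple(intervals), np.array(n_cov), np.array(gain), np.array(loss)
    )


def compare_groups(patient_table: pd.DataFrame) -> GroupComparison:
    """One-way ANOVA on per-patient mean distances, with pairwise tests.

    With three or more groups the pairwise comparisons use the Tukey HSD
    adjustment; with exactly two groups they fall back to a two-sided
    Mann-Whitney rank test.
    """
    if not {"group", "mean_d"} <= set(patient_table.columns):
        raise ValueError("patient table needs 'group' and 'mean_d' columns")
    groups = sorted(set(patient_table["group"].astype(str)))
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    values = [
        patient_table.loc[patient_table["group"].astype(str) == g, "mean_d"].to_numpy(float)
        for g in groups
    ]
    for g, v in zip(groups, values):
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 patients")

    pooled = np.concatenate(values)
    degenerate = np.ptp(pooled) == 0.0
    if degenerate:
        f_stat, p_omnibus = 0.0, 1.0
    else:
        with np.errstate(invalid="ignore"):
            f_stat, p_omnibus = scipy.stats.f_oneway(*values)
        if not np.isfinite(p_omnibus):
            f_stat, p_omnibus = 0.0, 1.0

    rows = []
    if len(groups) == 2:
        if degenerate:
            p_adj = 1.0
        else:
            _, p_adj = scipy.stats.mannwhitneyu(
                values[0], values[1], alternative="two-sided"
            )
        rows.append(
            {"group_a": groups[0], "group_b": groups[1],
             "mean_diff": float(values[0].mean() - values[1].mean()),
             "p_adj": float(p_adj), "method": "rank"}
        )
    else:
        if degenerate:
            pvals = np.ones((len(groups), len(groups)))
        else:
            pvals = scipy.stats.tukey_hsd(*values).pvalue
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                rows.append(
                    {"group_a": groups[i], "group_b": groups[j],
                     "mean_diff": float(values[i].mean() - values[j].mean()),
                     "p_adj": float(np.clip(pvals[i, j], 0.0, 1.0)),
                     "method": "tukey_hsd"}
                )

    summary = pd.DataFrame(
        {
            "group": groups,
            "n": [len(v) for v in values],
            "mean": [float(v.mean()) for v in values],
            "median": [float(np.median(v)) for v in values],
        }
    )
    return GroupComparison(
        tuple(groups), summary, float(f_stat), float(p_omnibus), pd.DataFrame(rows)
    )


@dataclass
class PipelineConfig:
    """Flat configuration for :func:`run_pipeline`.

    Either ``seg``/``sheet`` point at existing inputs, or ``simulate=True``
    generates a cohort first (using the sim_* fields).
    """

    out_dir: str = "cnclonal_out"
    seed: int = 0
    seg: str | None = None
    sheet: str | None = None
    chrom_sizes: str | None = None
    simulate: bool = False
    patients_per_mode: int = 5
    sim_n_chromosomes: int = 22
    sim_chromosome_length: int = 10_000_000
    sim_lattice: int = 100_000
    sim_ancestral_events: int = 5
    sim_subclones: int = 3
    sim_events_per_subclone: int = 5
    sim_purity_min: float = 0.4
    sim_purity_max: float = 0.9
    sim_noise_sd: float = 0.05
    sim_primaries: int = 1
    sim_metastases: int = 1
    grid_alpha_min: float = 0.20
    grid_alpha_max: float = 1.00
    grid_alpha_step: float = 0.01
    grid_tau_min: float = 1.50
    grid_tau_max: float = 5.00
    grid_tau_step: float = 0.01
    strategy: str = "coarse_to_fine"
    weights: str = "bp"
    normalize: bool = True
    autosomes_only: bool = True
    gain_threshold: float = 0.1
    loss_threshold: float = -0.1
    bin_size: int = 100_000
    log_level: str = "info"

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: configuration must be a flat mapping")
        return cls.from_dict(data)

    @property
    def grid(self) -> SearchGrid:
        return SearchGrid(
            self.grid_alpha_min, self.grid_alpha_max, self.grid_alpha_step,
            self.grid_tau_min, self.grid_tau_max, self.grid_tau_step,
        )

    @property
    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            seed=self.seed,
            n_chromosomes=self.sim_n_chromosomes,
            chromosome_length=self.sim_chromosome_length,
            breakpoint_lattice=self.sim_lattice,
            n_ancestral_events=self.sim_ancestral_events,
            n_subclones=self.sim_subclones,
            n_events_per_subclone=self.sim_events_per_subclone,
            purity_min=self.sim_purity_min,
            purity_max=self.sim_purity_max,
            noise_sd=self.sim_noise_sd,
            n_primary=self.sim_primaries,
            n_metastasis=self.sim_metastases,
        )


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f", lineterminator="\n")


def _setup_logging(out_dir: Path, level: str) -> None:
    numeric = getattr(logging, level.upper(), None)
    if numeric is None:
        raise ValueError(f"unknown log level {level!r}")
    logger.setLevel(numeric)
    logger.handlers = [logging.StreamHandler(), logging.FileHandler(out_dir / "run.log", mode="w")]
    fmt = logging.Formatter("%(levelname)s %(name)s: %(message)s")
    for h in logger.handlers:
        h.setFormatter(fmt)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run simulate/load, CNH, distances, frequency and group comparison.

    Writes ``cnh.tsv``, ``distances.tsv``, ``pairs.tsv``, ``frequency.tsv``,
    ``comparison.tsv`` and ``run.log`` into the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, config.log_level)
    grid = config.grid
    logger.info(
        "grid: %d purity x %d ploidy values; strategy=%s; numpy=%s scipy=%s",
        len(grid.alphas), len(grid.taus), config.strategy,
        np.__version__, scipy.__version__,
    )

    stage = "load"
    t0 = time.perf_counter()
    try:
        if config.simulate:
            stage = "simulate"
            seg_path, sheet_path, _ = simulate_cohort(
                config.simulation_config, config.patients_per_mode, config.seed, out
            )
        else:
            if not config.seg or not config.sheet:
                raise ValueError("provide 'seg' and 'sheet' paths or set simulate=true")
            seg_path, sheet_path = Path(config.seg), Path(config.sheet)
            if not seg_path.exists():
                raise FileNotFoundError(f"SEG file not found: {seg_path}")
            if not Path(sheet_path).exists():
                raise FileNotFoundError(f"sample sheet not found: {sheet_path}")
        stage = "read"
        if config.chrom_sizes:
            genome = GenomeModel.from_chrom_sizes(config.chrom_sizes)
        else:
            genome = infer_genome_from_seg(seg_path)
        profiles = read_seg(seg_path, genome)
        sheet = pd.read_csv(sheet_path, sep="\t", dtype=str)
        if config.autosomes_only:
            profiles = {k: restrict_to_autosomes(p) for k, p in profiles.items()}
        logger.info("loaded %d profiles, %d sheet rows [%.2fs]",
                    len(profiles), len(sheet), time.perf_counter() - t0)

        stage = "cnh"
        t0 = time.perf_counter()
        cnh_rows = []
        for sid in sorted(profiles):
            res = cnh_minimize(
                profiles[sid], grid,
                normalize=config.normalize, weight_mode=config.weights,
            )
            cnh_rows.append(
                {"sample_id": sid, "cnh": res.cnh, "alpha_hat": res.best.purity,
                 "tau_hat": res.best.ploidy, "n_ties": res.n_ties}
            )
        _write_table(pd.DataFrame(cnh_rows), out / "cnh.tsv")
        logger.info("cnh done [%.2fs]", time.perf_counter() - t0)

        stage = "distance"
        t0 = time.perf_counter()
        patients, pair_detail = cohort_distances(
            sheet, profiles, grid, config.strategy, normalize=config.normalize
        )
        _write_table(patients, out / "distances.tsv")
        _write_table(pair_detail, out / "pairs.tsv")
        logger.info("distances done for %d patients [%.2fs]",
                    len(patients), time.perf_counter() - t0)

        stage = "frequency"
        t0 = time.perf_counter()
        track = aberration_frequency(
            profiles.values(), config.gain_threshold, config.loss_threshold,
            config.bin_size,
        )
        _write_table(track.to_frame(), out / "frequency.tsv")
        logger.info("frequency done over %d bins [%.2fs]",
                    len(track.intervals), time.perf_counter() - t0)

        stage = "comparison"
        t0 = time.perf_counter()
        n_groups = patients["group"].nunique()
        counts = patients.groupby("group").size()
        if n_groups >= 2 and (counts >= 2).all():
            cmp = compare_groups(patients)
            rows = [
                {"kind": "group", "group_a": g, "group_b": "", "n": int(n),
                 "statistic": float(mean), "p_value": float("nan"),
                 "extra": float(median)}
                for g, n, mean, median in cmp.summary.itertuples(index=False)
            ]
            rows.append(
                {"kind": "omnibus", "group_a": "", "group_b": "", "n": len(patients),
                 "statistic": cmp.f_stat, "p_value": cmp.p_omnibus, "extra": float("nan")}
            )
            for r in cmp.pairwise.itertuples(index=False):
                rows.append(
                    {"kind": "pairwise", "group_a": r.group_a, "group_b": r.group_b,
                     "n": 0, "statistic": r.mean_diff, "p_value": r.p_adj,
                     "extra": float("nan")}
                )
            _write_table(pd.DataFrame(rows), out / "comparison.tsv")
        else:
            logger.warning("skipping group comparison: need >= 2 groups with >= 2 patients")
        logger.info("comparison done [%.2fs]", time.perf_counter() - t0)
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return out
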