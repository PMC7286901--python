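"""Synthetic datasets with known ground truth for every pipeline input.

Each generator emulates the statistical structure of one assay:

* amplicon count tables — multinomial sampling of mutant frequencies under
  exponential growth selection, with a smooth positional coverage bias so
  that coverage normalization is actually exercised;
* chase series — the closed-form arrest-chase model sampled at gel time
  points with multiplicative log-normal noise;
* refolding traces and melt curves — rising exponential and two-state
  transition with linear baselines, multiplicative noise at a chosen
  signal-to-noise ratio;
* growth matrices — Hill-type growth suppression across an antibiotic
  dilution series with a known true MIC;
* event tables — log-normal two-channel fluorescence events.

All randomness flows through one ``numpy.random.default_rng(seed)`` per
call, so a fixed seed reproduces a dataset exactly; every generator returns
the dataset together with a JSON-serializable ``truth`` dict holding the
generating parameters (enough to regenerate the dataset bit-for-bit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dms import MutantCountTable
from .kinetics import KineticTrace
from .mic import GrowthMatrix
from .sim import SimParams, closed_form_chase

__all__ = [
    "GeneratorConfig",
    "SyntheticCounts",
    "gen_count_table",
    "gen_chase_series",
    "gen_refolding_trace",
    "gen_melt_curve",
    "gen_growth_matrix",
    "gen_event_table",
]

#: chase sampling times (minutes post-arrest) used by gel-based chases
CHASE_TIME_POINTS_MIN = (0.0, 15.0, 30.0, 60.0, 120.0)

#: two-fold gentamicin dilution series, µg/ml (0 = unselected anchor)
DEFAULT_CONCENTRATIONS = (0.0, 12.5, 25.0, 50.0, 100.0, 200.0, 400.0, 800.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the selection-count generator (and shared noise levels).

    Defaults describe a pooled gentamicin selection of a ~100-member
    glycine-doublet mutant panel on a 500 bp amplicon, sequenced to 10^6
    reads per sample in two biological replicates: frequencies start from a
    near-homogeneous Dirichlet pool, selection reweights them by
    ``exp(fitness * generations)`` over ~10 generations of growth, and the
    per-position coverage carries a smooth low-order polynomial bias.
    """

    seed: int = 0
    n_mutants: int = 100
    gene_length: int = 500
    depth: int = 1_000_000
    n_replicates: int = 2
    strains: tuple = ("CSH4", "WG350")
    generations: float = 10.0
    fitness_log_range: float = 2.0   # spread of fitness*generations, nat-log units
    # pre-selection evenness: designed mutant libraries are close to
    # homogeneously covered, so the default Dirichlet gives ~10% frequency CV
    dirichlet_alpha: float = 100.0
    coverage_bias_coeffs: tuple = (1.3, -0.9, 0.6)  # polynomial in pos/length
    count_dispersion: float = 0.0    # >0 switches on Dirichlet-multinomial
    planted_log_fold: Optional[Mapping[str, float]] = None  # mutant -> log-fold
    planted_strain: Optional[str] = None  # defaults to the last strain
    trace_snr: float = 20.0
    od_noise: float = 0.0
    chase_time_points: tuple = CHASE_TIME_POINTS_MIN
    concentration_grid: tuple = DEFAULT_CONCENTRATIONS

    def __post_init__(self):
        if self.n_mutants < 1 or self.gene_length < 1 or self.depth < 1:
            raise ValueError("n_mutants, gene_length and depth must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name in ("count_dispersion", "od_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.trace_snr <= 0:
            raise ValueError("trace_snr must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["planted_log_fold"] is not None:
            d["planted_log_fold"] = dict(d["planted_log_fold"])
        return d


@dataclass
class SyntheticCounts:
    """A generated count dataset plus its generating truth."""

    table: MutantCountTable
    truth: dict

    def write(self, out_dir) -> None:
        """Emit counts.tsv / coverage.tsv / samples.tsv / truth.json."""
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.counts.to_csv(out / "counts.tsv", sep="\t", index=False)
        self.table.coverage.to_csv(out / "coverage.tsv", sep="\t", index=False)
        self.table.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
        (out / "truth.json").write_text(json.dumps(self.truth, indent=1, sort_keys=True))


def _coverage_bias(cfg: GeneratorConfig, positions: np.ndarray) -> np.ndarray:
    u = positions / cfg.gene_length
    c = cfg.coverage_bias_coeffs
    bias = sum(ci * u**i for i, ci in enumerate(c))
    if np.any(bias <= 0):
        raise ValueError("coverage bias profile must stay positive")
    return bias


def gen_count_table(cfg: GeneratorConfig, seed: Optional[int] = None) -> SyntheticCounts:
    """Simulate a selection experiment as a mutant count table.

    Pre-selection mutant frequencies are Dirichlet-distributed; selected
    samples reweight them by ``exp(f_m * generations)`` where ``f_m`` is the
    mutant's growth advantage (drawn uniformly so that ``f*T`` spans
    ``fitness_log_range`` natural-log units, shared across strains).  Counts
    are multinomial draws at ``depth`` reads per sample over frequencies
    tilted by the positional coverage bias; per-position coverage is the
    depth times the same bias, so coverage normalization removes it.
    Optional ``planted_log_fold`` applies a natural-log fold-change to the
    chosen mutants in the selected samples of ``planted_strain`` (last
    strain by default) — the ground truth for cross-strain buffering calls.

    Returns a :class:`SyntheticCounts`; ``truth`` holds the fitness vector,
    the pre-selection frequencies, the plant and the full config, enough to
    regenerate the dataset exactly.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = cfg.n_mutants
    mutants = np.array([f"m{i:04d}" for i in range(n)])
    # evenly spaced positions across the amplicon (1-based)
    positions = 1 + (np.arange(n) * cfg.gene_length) // n
    bias = _coverage_bias(cfg, positions)

    p0 = rng.dirichlet(np.full(n, cfg.dirichlet_alpha))
    f_times_T = rng.uniform(-0.5, 0.5, n) * cfg.fitness_log_range
    fitness = f_times_T / cfg.generations

    planted_strain = cfg.planted_strain or cfg.strains[-1]
    planted = dict(cfg.planted_log_fold or {})
    unknown = set(planted) - set(mutants)
    if unknown:
        raise ValueError(f"planted mutants not in panel: {sorted(unknown)}")

    counts_rows, cov_rows, sample_rows = [], [], []
    for strain in cfg.strains:
        for condition in ("unselected", "selected"):
            freq = p0.copy()
            if condition == "selected":
                freq = freq * np.exp(f_times_T)
                if strain == planted_strain and planted:
                    shift = np.array([planted.get(m, 0.0) for m in mutants])
                    freq = freq * np.exp(shift)
            freq = freq / freq.sum()
            q = freq * bias
            q = q / q.sum()
            for rep in range(1, cfg.n_replicates + 1):
                sample = f"{strain}_{condition}_r{rep}"
                sample_rows.append(
                    {"sample": sample, "strain": strain,
                     "condition": condition, "replicate": rep}
                )
                draw_q = q
                if cfg.count_dispersion > 0:
                    draw_q = rng.dirichlet(q / cfg.count_dispersion)
                counts = rng.multinomial(cfg.depth, draw_q)
                counts_rows.append(pd.DataFrame({
                    "mutant_id": mutants, "position": positions,
                    "sample": sample, "count": counts,
                }))
                cov = np.ceil(cfg.depth * bias).astype(np.int64)
                # coverage can never undercut the reads actually observed
                per_pos = pd.Series(counts).groupby(pd.Series(positions)).sum()
                cov = np.maximum(cov, per_pos.reindex(positions).to_numpy())
                cov_rows.append(pd.DataFrame({
                    "sample": sample, "position": positions, "coverage": cov,
                }).drop_duplicates("position"))

    table = MutantCountTable(
        counts=pd.concat(counts_rows, ignore_index=True),
        coverage=pd.concat(cov_rows, ignore_index=True),
        samples=pd.DataFrame(sample_rows),
    )
    truth = {
        "seed": int(seed),
        "config": cfg.to_dict(),
        "mutants": mutants.tolist(),
        "positions": positions.tolist(),
        "p0": p0.tolist(),
        "fitness": dict(zip(mutants.tolist(), fitness.tolist())),
        "generations": cfg.generations,
        "planted_log_fold": planted,
        "planted_strain": planted_strain,
    }
    return SyntheticCounts(table=table, truth=truth)


def _mult_noise(rng, shape, sigma):
    """Multiplicative log-normal noise factors, exp(N(0, sigma))."""
    if sigma == 0:
        return np.ones(shape)
    return np.exp(rng.normal(0.0, sigma, shape))


def gen_chase_series(
    params: SimParams,
    time_points_min: Sequence[float] = CHASE_TIME_POINTS_MIN,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[KineticTrace, dict]:
    """Sample a chase decay from the closed-form arrest model.

    ``time_points_min`` are minutes after the arrest; the intact (U+F)
    signal is normalized to the arrest time point and perturbed by
    multiplicative log-normal noise of s.d. ``noise``.  The returned truth
    carries the exact normalized values and the model parameters.
    """
    tp = np.asarray(time_points_min, dtype=float)
    if np.any(tp < 0) or np.any(np.diff(tp) <= 0):
        raise ValueError("time points must be increasing and >= 0")
    t_abs = params.t_arrest + 60.0 * tp
    state = closed_form_chase(params, t_abs)
    anchor = closed_form_chase(params, params.t_arrest).intact
    exact = state.intact / anchor
    rng = np.random.default_rng(seed)
    y = exact * _mult_noise(rng, exact.shape, noise)
    trace = KineticTrace(x=tp, y=y, kind="chase")
    truth = {
        "params": params.to_dict(), "time_points_min": tp.tolist(),
        "exact_normalized": np.asarray(exact).tolist(),
        "noise": noise, "seed": int(seed),
    }
    return trace, truth


def gen_refolding_trace(
    k: float,
    *,
    t_max: float = 900.0,
    n_points: int = 181,
    baseline: float = 100.0,
    amplitude: float = 1000.0,
    snr: float = 20.0,
    seed: int = 0,
) -> tuple[KineticTrace, dict]:
    """Rising-exponential refolding trace ``y0 + A (1 - exp(-k t))``.

    ``snr`` sets the multiplicative noise level (s.d. 1/snr per point);
    the default 15-minute, 5-second-interval acquisition resolves rates in
    the 1e-3 ... 1e-1 s^-1 range typical of spontaneous GFP refolding.
    """
    if k < 0:
        raise ValueError("rate k must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_max, n_points)
    exact = baseline + amplitude * -np.expm1(-k * t)
    y = exact * _mult_noise(rng, exact.shape, 1.0 / snr if snr != np.inf else 0.0)
    trace = KineticTrace(x=t, y=y, kind="refolding")
    truth = {"k": k, "baseline": baseline, "amplitude": amplitude,
             "snr": snr, "t_max": t_max, "n_points": n_points, "seed": int(seed)}
    return trace, truth


def gen_melt_curve(
    tm: float,
    *,
    width: float = 1.5,
    t_start: float = 25.0,
    t_end: float = 90.0,
    step: float = 1.0,
    native: tuple = (1200.0, -3.0),
    unfolded: tuple = (150.0, 0.5),
    snr: float = 20.0,
    seed: int = 0,
) -> tuple[KineticTrace, dict]:
    """Two-state melt curve on a temperature ramp (default 25-90 °C, 1 °C).

    Fluorescence is high on the sloped native baseline and collapses to the
    unfolded baseline through a logistic transition of the given ``width``
    centred at ``tm``.
    """
    if not t_start < tm < t_end:
        raise ValueError("tm must lie inside the scanned temperature range")
    rng = np.random.default_rng(seed)
    T = np.arange(t_start, t_end + step / 2, step)
    theta = 1.0 / (1.0 + np.exp((T - tm) / width))
    exact = (native[0] + native[1] * T) * theta + (unfolded[0] + unfolded[1] * T) * (1 - theta)
    y = exact * _mult_noise(rng, exact.shape, 1.0 / snr if snr != np.inf else 0.0)
    trace = KineticTrace(x=T, y=y, kind="melt")
    truth = {"tm": tm, "width": width, "native": list(native),
             "unfolded": list(unfolded), "snr": snr, "seed": int(seed),
             "t_start": t_start, "t_end": t_end, "step": step}
    return trace, truth


def gen_growth_matrix(
    true_mic: Mapping[tuple, float],
    *,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    threshold: float = 0.1,
    hill: float = 8.0,
    od0: float = 0.8,
    n_replicates: int = 4,
    noise: float = 0.0,
    wt_mutant: str = "Wt",
    crossing: float = 0.7071067811865476,
    seed: int = 0,
) -> tuple[GrowthMatrix, dict]:
    """Hill-type growth suppression with a known MIC per (strain, mutant).

    ``true_mic[(strain, mutant)]`` is the concentration at which the assay
    reads out suppression: the continuous threshold crossing of the Hill
    curve is placed at ``crossing * true_mic`` (default half a two-fold
    dilution step below, i.e. mic/sqrt(2)), so growth at the MIC is
    comfortably below threshold and at the next lower dilution comfortably
    above it.  The noise-free grid call therefore returns ``true_mic``
    exactly when it lies on the tested grid — the smallest grid
    concentration above the continuous crossing — and stays correct under
    moderate OD noise.  OD noise is multiplicative log-normal.
    """
    if not 0 < crossing <= 1:
        raise ValueError("crossing must be in (0, 1]")
    conc = np.asarray(sorted(concentrations), dtype=float)
    if conc[0] != 0:
        raise ValueError("concentration grid must include 0 (unselected anchor)")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    truth_entries = {}
    for (strain, mutant), mic in true_mic.items():
        if mic <= 0:
            raise ValueError("true MIC values must be positive")
        c_star = mic * crossing
        c50 = c_star / ((1.0 - threshold) / threshold) ** (1.0 / hill)
        with np.errstate(divide="ignore"):
            frac = 1.0 / (1.0 + (conc / c50) ** hill)
        for rep in range(1, n_replicates + 1):
            od = od0 * frac * _mult_noise(rng, conc.shape, noise)
            od[0] = od0 * _mult_noise(rng, (), noise)  # unselected anchor well
            rows.append(pd.DataFrame({
                "strain": strain, "mutant": mutant, "replicate": rep,
                "concentration": conc, "od600": od,
            }))
        truth_entries[f"{strain}|{mutant}"] = {
            "true_mic": float(mic), "c50": float(c50), "hill": hill,
            "threshold_crossing": float(c_star),
        }
    matrix = GrowthMatrix(pd.concat(rows, ignore_index=True), wt_mutant=wt_mutant)
    truth = {
        "entries": truth_entries, "threshold": threshold, "od0": od0,
        "concentrations": conc.tolist(), "n_replicates": n_replicates,
        "noise": noise, "seed": int(seed), "wt_mutant": wt_mutant, "hill": hill,
        "crossing": crossing,
    }
    return matrix, truth


def gen_event_table(
    n_events: int = 10_000,
    *,
    gfp_log_median: float = 0.0,
    gfp_log_sigma: float = 0.5,
    mcherry_log_median: float = 0.0,
    mcherry_log_sigma: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Two-channel log-normal cytometry-style events.

    Channel medians are ``exp(log_median)``; the per-event GFP/mCherry
    ratio is again log-normal with log-median equal to the difference of
    the channel log-medians.
    """
    if n_events < 1:
        raise ValueError("n_events must be positive")
    rng = np.random.default_rng(seed)
    gfp = np.exp(rng.normal(gfp_log_median, gfp_log_sigma, n_events))
    mch = np.exp(rng.normal(mcherry_log_median, mcherry_log_sigma, n_events))
    df = pd.DataFrame({"gfp": gfp, "mcherry": mch})
    truth = {
        "n_events": n_events,
        "gfp_log_median": gfp_log_median, "gfp_log_sigma": gfp_log_sigma,
        "mcherry_log_median": mcherry_log_median,
        "mcherry_log_sigma": mcherry_log_sigma,
        "true_median_ratio": float(np.exp(gfp_log_median - mcherry_log_median)),
        "seed": int(seed),
    }
    return df, truth
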