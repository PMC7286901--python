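"""End-to-end synthetic demonstration run.

Wires the generators and analysis stages into one reproducible run: a
selection count table with a planted buffering-reduced mutant is scored and
cross-strain flagged; a folding-rate scan of the arrest-chase model maps
intact protein against k_f; a growth matrix yields MICs and percent-MICs;
refolding/melt/chase traces are fitted; a reporter event table is
summarized.  Everything is seeded from one integer and every table is
written with a fixed float format, so re-running with the same manifest
reproduces the outputs byte for byte (plots are advisory; all numbers live
in the tables).
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import __version__
from ._exceptions import BufferscanError
from .dms import score_table
from .kinetics import (
    fit_chase_decay,
    fit_melt_tm,
    fit_refolding_rate,
    summarize_fluorescence_ratio,
)
from .mic import mic_table
from .sim import SimParams, scan_folding_rates
from .synthetic import (
    GeneratorConfig,
    gen_chase_series,
    gen_count_table,
    gen_event_table,
    gen_growth_matrix,
    gen_melt_curve,
    gen_refolding_trace,
)

__all__ = ["RunConfig", "run_end_to_end", "PipelineStageError"]

log = logging.getLogger("bufferscan")

_FLOAT_FMT = "%.10g"


class PipelineStageError(BufferscanError):
    """A pipeline stage failed; partial outputs are left in place."""

    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a demo run; unknown keys are rejected up front."""

    seed: int = 17
    out_dir: str = "demo"
    n_mutants: int = 100
    depth: int = 200_000
    planted_mutant: str = "m0042"
    planted_log_fold: float = -2.302585092994046  # ln(1/10): 10-fold reduced
    kf_values: tuple = (1e-4, 3e-4, 1e-3, 3e-3, 1e-2, 3e-2, 1e-1, 3e-1, 1.0)
    t_end: float = 1200.0
    n_points: int = 601
    readout_time: float = 1200.0
    ci_level: float = 0.99
    make_plots: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "kf_values" in d:
            d = {**d, "kf_values": tuple(float(v) for v in d["kf_values"])}
        return cls(**d)


def _write_tsv(df: pd.DataFrame, path: pathlib.Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _sha256(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage name must surface
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


@_stage("dms_scoring")
def _run_dms(cfg: RunConfig, seed: int, out: pathlib.Path) -> dict:
    gen_cfg = GeneratorConfig(
        seed=seed, n_mutants=cfg.n_mutants, depth=cfg.depth,
        planted_log_fold={cfg.planted_mutant: cfg.planted_log_fold},
    )
    data = gen_count_table(gen_cfg)
    data.write(out / "inputs")
    result = score_table(data.table, ci_level=cfg.ci_level)
    scores = result["scores"]
    comp = next(iter(result["comparisons"].values()))
    comp_name = next(iter(result["comparisons"]))
    flags = comp.flags.rename(f"flag_{comp_name}")
    merged = scores.merge(flags, left_on="mutant_id", right_index=True, how="left")
    _write_tsv(merged, out / "scores.tsv")
    (out / "band.json").write_text(
        json.dumps({comp_name: comp.band_parameters()}, indent=1, sort_keys=True)
    )
    reduced = list(comp.flags.index[comp.flags == "reduced"])
    return {
        "scores_path": "scores.tsv",
        "comparison": comp_name,
        "reduced_mutants": reduced,
        "planted_mutant": cfg.planted_mutant,
        "planted_flagged": cfg.planted_mutant in reduced,
        "n_flagged": comp.n_flagged,
        "_comparison_obj": comp,
    }


@_stage("folding_rate_scan")
def _run_scan(cfg: RunConfig, out: pathlib.Path) -> dict:
    params = SimParams()
    t_grid = np.linspace(0.0, cfg.t_end, cfg.n_points)
    scan = scan_folding_rates(params, cfg.kf_values, t_grid)
    intact = scan.intact_at(cfg.readout_time)
    df = pd.DataFrame({"k_f": scan.kf_values, "intact_at_readout": intact})
    _write_tsv(df, out / "kf_scan.tsv")
    _write_tsv(scan.to_frame(), out / "kf_trajectories.tsv")
    return {
        "kf_scan_path": "kf_scan.tsv",
        "monotone_in_kf": bool(np.all(np.diff(intact) >= -1e-9 * intact.max())),
        "_scan_obj": scan,
    }


@_stage("mic")
def _run_mic(cfg: RunConfig, seed: int, out: pathlib.Path) -> dict:
    true_mic = {}
    for strain in ("CSH4", "WG350"):
        true_mic[(strain, "Wt")] = 400.0
        true_mic[(strain, "GG1")] = 100.0 if strain == "CSH4" else 25.0
        true_mic[(strain, "GG2")] = 200.0 if strain == "CSH4" else 50.0
    matrix, truth = gen_growth_matrix(true_mic, noise=0.05, seed=seed)
    table = mic_table(matrix)
    _write_tsv(table, out / "mic.tsv")
    (out / "mic_truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    wt_rows = table[table["mutant"] == "Wt"]
    return {
        "mic_path": "mic.tsv",
        "wt_percent_mic": wt_rows["percent_mic"].tolist(),
    }


@_stage("kinetic_fits")
def _run_fits(cfg: RunConfig, seed: int, out: pathlib.Path) -> dict:
    rows = []
    # refolding pair: wild-type-like rate and a 10-fold slower mutant
    for offset, (name, k) in enumerate((("Wt", 1e-2), ("C1", 1e-3))):
        # acquire until the rise is essentially complete (~5 half-lives)
        trace, truth = gen_refolding_trace(k, t_max=5.0 / k, snr=20.0,
                                           seed=seed + offset)
        fit = fit_refolding_rate(trace)
        rows.append({"assay": "refolding", "series": name,
                     "parameter": "k_per_s", "value": fit["k"],
                     "stderr": fit.stderr["k"], "truth": k})
    melt_trace, melt_truth = gen_melt_curve(72.0, snr=20.0, seed=seed + 7)
    fit = fit_melt_tm(melt_trace)
    rows.append({"assay": "melt", "series": "C1", "parameter": "Tm_C",
                 "value": fit["Tm"], "stderr": fit.stderr["Tm"],
                 "truth": melt_truth["tm"]})
    for name, kf in (("slow_folder", 1e-3), ("fast_folder", 3e-2)):
        params = SimParams(k_f=kf)
        trace, truth = gen_chase_series(params, noise=0.05, seed=seed + 11)
        # total-loss rate (plateau pinned at 0): the quantity that falls as
        # folding speeds up, mirroring the chase-gel reading
        fit = fit_chase_decay(trace, fix_plateau=True)
        rows.append({"assay": "chase", "series": name,
                     "parameter": "k_app_per_min", "value": fit["k_app"],
                     "stderr": fit.stderr["k_app"], "truth": np.nan})
    df = pd.DataFrame(rows)
    _write_tsv(df, out / "fits.tsv")
    ref = df[df["assay"] == "refolding"].set_index("series")["value"]
    chase = df[df["assay"] == "chase"].set_index("series")["value"]
    return {
        "fits_path": "fits.tsv",
        "refolding_rate_ratio": float(ref["Wt"] / ref["C1"]),
        "chase_rate_ordering_ok": bool(
            chase["slow_folder"] > chase["fast_folder"]
        ),
    }


@_stage("fluorescence_ratio")
def _run_ratio(cfg: RunConfig, seed: int, out: pathlib.Path) -> dict:
    events, truth = gen_event_table(
        10_000, gfp_log_median=0.6931471805599453, seed=seed  # true ratio 2
    )
    _write_tsv(events, out / "events.tsv")
    summary = summarize_fluorescence_ratio(events, reference_median=1.0)
    result = {
        "median_ratio": summary.median_ratio,
        "log2_fold_change": summary.log2_fold_change,
        "n_events": summary.n_events,
        "true_median_ratio": truth["true_median_ratio"],
    }
    (out / "ratio.json").write_text(json.dumps(result, indent=1, sort_keys=True))
    return result


def _plots(out: pathlib.Path, scan_info: dict, dms_info: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scan = scan_info["_scan_obj"]
    df = pd.read_csv(out / "kf_scan.tsv", sep="\t")
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.semilogx(df["k_f"], df["intact_at_readout"], "o-")
    ax.set_xlabel("folding rate k_f (s$^{-1}$)")
    ax.set_ylabel("intact protein at readout (µM)")
    ax.set_title("intact protein vs folding rate")
    fig.tight_layout()
    fig.savefig(out / "kf_scan.png", dpi=120)
    plt.close(fig)
    del scan

    comp = dms_info["_comparison_obj"]
    t = comp.table.sort_values("log_a")
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.fill_between(t["log_a"], t["lower"], t["upper"], alpha=0.25,
                    color="pink", label=f"{comp.ci_level:.0%} band")
    colors = comp.flags.loc[t.index].map(
        {"concordant": "0.4", "reduced": "crimson", "enhanced": "royalblue"}
    )
    ax.scatter(t["log_a"], t["log_b"], s=12, c=colors)
    ax.set_xlabel("ln normalized count, strain A")
    ax.set_ylabel("ln normalized count, strain B")
    ax.legend(loc="upper left")
    fig.tight_layout()
    fig.savefig(out / "strain_comparison.png", dpi=120)
    plt.close(fig)


def run_end_to_end(cfg: RunConfig) -> dict:
    """Run the full synthetic demonstration; returns the report dict.

    Writes tables, truth sidecars, advisory plots and a ``manifest.json``
    (config, package version, SHA-256 of every table) under
    ``cfg.out_dir``.  Stage failures raise :class:`PipelineStageError`
    naming the stage, leaving earlier outputs in place.
    """
    out = pathlib.Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=8)

    dms_info = _run_dms(cfg, int(sub_seeds[0]), out)
    scan_info = _run_scan(cfg, out)
    mic_info = _run_mic(cfg, int(sub_seeds[1]), out)
    fit_info = _run_fits(cfg, int(sub_seeds[2]), out)
    ratio_info = _run_ratio(cfg, int(sub_seeds[3]), out)
    if cfg.make_plots:
        _plots(out, scan_info, dms_info)

    report = {
        "config": asdict(cfg),
        "dms": {k: v for k, v in dms_info.items() if not k.startswith("_")},
        "folding_scan": {k: v for k, v in scan_info.items() if not k.startswith("_")},
        "mic": mic_info,
        "fits": fit_info,
        "ratio": ratio_info,
    }
    tables = sorted(
        p for p in out.rglob("*")
        if p.suffix in (".tsv", ".json") and p.name not in ("manifest.json", "report.json")
    )
    manifest = {
        "config": asdict(cfg),
        "version": __version__,
        "checksums": {str(p.relative_to(out)): _sha256(p) for p in tables},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
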