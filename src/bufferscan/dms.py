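"""Deep-mutational-scanning enrichment scoring and cross-strain comparison.

The pipeline starts from per-mutant amplicon read counts (one selection
experiment per sample) and proceeds:

1. coverage normalization — each mutant's count is divided by the total read
   coverage at its position in that sample, giving a depth-free frequency;
2. replicate averaging within each (strain, condition) group;
3. enrichment score ``E`` = normalized count under selection / normalized
   count without selection, a proxy for variant activity;
4. z-scoring of ``E`` across the mutant panel (sample standard deviation),
   with three activity classes: more active than average, near average,
   less active than average;
5. cross-strain comparison of per-mutant normalized counts on the log scale,
   flagging mutants that fall outside an ordinary-least-squares prediction
   band (default 99%) as buffered differently (``reduced`` / ``enhanced``).

A pseudocount (default 0.5 reads) keeps zero-count mutants finite through
the ratio steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._exceptions import DataError, DegenerateDataError

__all__ = [
    "MutantCountTable",
    "StrainComparison",
    "normalize_counts",
    "replicate_mean",
    "enrichment_scores",
    "zscore_classify",
    "compare_strains",
]

DEFAULT_PSEUDOCOUNT = 0.5

COUNT_COLUMNS = ("mutant_id", "position", "sample", "count")
COVERAGE_COLUMNS = ("sample", "position", "coverage")
SAMPLE_COLUMNS = ("sample", "strain", "condition", "replicate")
CONDITIONS = ("selected", "unselected")


@dataclass
class MutantCountTable:
    """Per-mutant read counts with positional coverage and sample metadata.

    Attributes
    ----------
    counts : DataFrame with columns mutant_id, position, sample, count.
    coverage : DataFrame with columns sample, position, coverage.
    samples : DataFrame with columns sample, strain, condition, replicate;
        condition is "selected" or "unselected".
    """

    counts: pd.DataFrame
    coverage: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        for df, cols, name in (
            (self.counts, COUNT_COLUMNS, "counts"),
            (self.coverage, COVERAGE_COLUMNS, "coverage"),
            (self.samples, SAMPLE_COLUMNS, "samples"),
        ):
            missing = set(cols) - set(df.columns)
            if missing:
                raise DataError(f"{name} table missing columns {sorted(missing)}")
        if (self.counts["count"] < 0).any():
            raise DataError("negative read counts")
        if (self.coverage["coverage"] <= 0).any():
            raise DataError("coverage must be positive")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise DataError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
        unknown_samples = set(self.counts["sample"]) - set(self.samples["sample"])
        if unknown_samples:
            raise DataError(
                f"count samples missing from sample sheet: {sorted(unknown_samples)}"
            )
        self._check_count_le_coverage()

    def _check_count_le_coverage(self):
        merged = self.counts.merge(
            self.coverage, on=["sample", "position"], how="left", validate="m:1"
        )
        missing = merged["coverage"].isna()
        if missing.any():
            first = merged.loc[missing, ["sample", "position"]].iloc[0]
            raise DataError(
                "missing coverage for sample "
                f"{first['sample']!r} position {int(first['position'])}"
            )
        over = merged["count"] > merged["coverage"]
        if over.any():
            first = merged.loc[over].iloc[0]
            raise DataError(
                f"count exceeds coverage for mutant {first['mutant_id']!r} in "
                f"sample {first['sample']!r} at position {int(first['position'])}"
            )

    @classmethod
    def from_files(cls, counts_path, coverage_path, samples_path) -> "MutantCountTable":
        """Read the three TSV inputs (tab-separated, headered)."""
        return cls(
            counts=pd.read_csv(counts_path, sep="\t"),
            coverage=pd.read_csv(coverage_path, sep="\t"),
            samples=pd.read_csv(samples_path, sep="\t"),
        )


def normalize_counts(
    table: MutantCountTable, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Coverage-normalize counts: (count + pseudocount) / coverage(position).

    Returns a long DataFrame (mutant_id, position, sample, normalized).  The
    result is invariant under uniform rescaling of sequencing depth, because
    count and coverage scale together.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    merged = table.counts.merge(
        table.coverage, on=["sample", "position"], how="left", validate="m:1"
    )
    merged["normalized"] = (merged["count"] + pseudocount) / merged["coverage"]
    return merged[["mutant_id", "position", "sample", "normalized"]]


def replicate_mean(
    normalized: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Average normalized counts across replicates per (strain, condition).

    Returns one row per (mutant_id, strain, condition) with columns
    ``mean_normalized``, ``n_replicates`` and boolean flags ``partial``
    (mutant missing from some replicates of the group — averaged over the
    present ones, never silently dropped) and ``single_replicate``.
    """
    if len(samples) == 0:
        raise ValueError("empty sample sheet")
    merged = normalized.merge(samples, on="sample", validate="m:1")
    group_sizes = (
        samples.groupby(["strain", "condition"])["sample"].nunique().rename("n_total")
    )
    out = (
        merged.groupby(["mutant_id", "strain", "condition"], sort=True)["normalized"]
        .agg(mean_normalized="mean", n_replicates="count")
        .reset_index()
        .merge(group_sizes, on=["strain", "condition"])
    )
    out["partial"] = out["n_replicates"] < out["n_total"]
    out["single_replicate"] = out["n_total"] == 1
    return out.drop(columns="n_total")


def _as_series(values) -> pd.Series:
    s = pd.Series(values, dtype=float) if not isinstance(values, pd.Series) else values
    return s.astype(float)


def enrichment_scores(selected, unselected) -> pd.Series:
    """Enrichment score E = selected / unselected frequency, per mutant.

    Both inputs are per-mutant normalized (pseudocounted, hence strictly
    positive) counts indexed by mutant id.
    """
    sel = _as_series(selected)
    unsel = _as_series(unselected)
    mismatch = sel.index.symmetric_difference(unsel.index)
    if len(mismatch):
        raise DataError(f"mutant keys differ between conditions: {list(mismatch)[:10]}")
    if (unsel <= 0).any() or (sel <= 0).any():
        offenders = list(unsel.index[(unsel <= 0)]) + list(sel.index[(sel <= 0)])
        raise DataError(
            f"non-positive normalized counts (apply a pseudocount): {offenders[:10]}"
        )
    E = (sel / unsel.reindex(sel.index)).rename("E")
    return E


def zscore_classify(
    E, high_cut: float = 1.0, low_cut: float = -1.0
) -> pd.DataFrame:
    """z-score enrichment scores and label activity classes.

    z = (E - mean(E)) / sd(E) with the sample (n-1) standard deviation,
    treating the panel as normally distributed.  Labels: z >= ``high_cut``
    -> ``more_active``, z <= ``low_cut`` -> ``less_active``, otherwise
    ``near_average``.
    """
    E = _as_series(E)
    if len(E) < 3:
        raise ValueError("need at least 3 mutants to z-score")
    if high_cut <= low_cut:
        raise ValueError("high_cut must exceed low_cut")
    sd = E.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateDataError("enrichment scores have zero dispersion")
    z = (E - E.mean()) / sd
    label = pd.Series("near_average", index=E.index, dtype=object)
    label[z >= high_cut] = "more_active"
    label[z <= low_cut] = "less_active"
    return pd.DataFrame({"E": E, "z": z.rename("z"), "label": label})


@dataclass
class StrainComparison:
    """Cross-strain normalized-count comparison with a prediction band.

    Per-mutant flags: ``reduced`` (below the lower band in strain B relative
    to strain A), ``enhanced`` (above the upper band) or ``concordant``.
    Fitted line and band are on the natural-log scale.
    """

    flags: pd.Series
    slope: float
    intercept: float
    ci_level: float
    band_kind: str  # "prediction" or "confidence"
    table: pd.DataFrame = field(repr=False)  # log_a, log_b, lower, upper

    @property
    def n_flagged(self) -> int:
        return int((self.flags != "concordant").sum())

    def band_parameters(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "ci_level": self.ci_level,
            "band_kind": self.band_kind,
            "log_scale": "natural",
        }


def compare_strains(
    mean_a,
    mean_b,
    ci_level: float = 0.99,
    *,
    band: str = "prediction",
) -> StrainComparison:
    """Compare per-mutant normalized counts between two strains.

    Fits an ordinary-least-squares line of log(B) on log(A) across the
    shared mutants and computes a band at ``ci_level``.  A mutant whose
    strain-B value falls below the lower band is flagged ``reduced`` (less
    buffered in B), above the upper band ``enhanced``, otherwise
    ``concordant``.

    ``band="prediction"`` (default) uses the OLS prediction interval for a
    new observation, which is the appropriate per-point outlier criterion;
    ``band="confidence"`` uses the narrower mean-response band.
    """
    a = _as_series(mean_a)
    b = _as_series(mean_b)
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared mutants")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    if band not in ("prediction", "confidence"):
        raise ValueError("band must be 'prediction' or 'confidence'")
    a, b = a.loc[shared], b.loc[shared]
    if (a <= 0).any() or (b <= 0).any():
        raise DataError("normalized counts must be positive (pseudocounted)")
    log_a = np.log(a.to_numpy())
    log_b = np.log(b.to_numpy())
    if np.ptp(log_a) == 0:
        raise DegenerateDataError("zero variance in strain-A counts")

    X = sm.add_constant(log_a)
    res = sm.OLS(log_b, X).fit()
    pred = res.get_prediction(X).summary_frame(alpha=1.0 - ci_level)
    if band == "prediction":
        lower, upper = pred["obs_ci_lower"].to_numpy(), pred["obs_ci_upper"].to_numpy()
    else:
        lower, upper = pred["mean_ci_lower"].to_numpy(), pred["mean_ci_upper"].to_numpy()

    flags = np.where(log_b < lower, "reduced",
                     np.where(log_b > upper, "enhanced", "concordant"))
    table = pd.DataFrame(
        {"log_a": log_a, "log_b": log_b, "lower": lower, "upper": upper},
        index=shared,
    )
    return StrainComparison(
        flags=pd.Series(flags, index=shared, name="flag"),
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        ci_level=ci_level,
        band_kind=band,
        table=table,
    )


def score_table(
    table: MutantCountTable,
    *,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    high_cut: float = 1.0,
    low_cut: float = -1.0,
    ci_level: float = 0.99,
) -> dict:
    """Run the full scoring pipeline on a count table.

    Per strain: enrichment scores E (selected vs unselected replicate
    means), z-scores and activity labels.  For every pair of strains the
    selection-condition normalized counts are additionally compared with
    :func:`compare_strains`.  Mutants absent from every replicate of a
    condition are reported with a ``dropout`` flag rather than a score.

    Returns a dict with keys ``scores`` (DataFrame, one row per
    strain × mutant), ``comparisons`` (mapping "A_vs_B" ->
    :class:`StrainComparison`) and ``dropouts`` (DataFrame).
    """
    normalized = normalize_counts(table, pseudocount)
    means = replicate_mean(normalized, table.samples)
    strains = sorted(table.samples["strain"].unique())

    all_mutants = pd.Index(sorted(table.counts["mutant_id"].unique()))
    frames, dropouts = [], []
    by_strain_sel = {}
    for strain in strains:
        sub = means[means["strain"] == strain]
        sel = sub[sub["condition"] == "selected"].set_index("mutant_id")["mean_normalized"]
        unsel = sub[sub["condition"] == "unselected"].set_index("mutant_id")["mean_normalized"]
        present = sel.index.intersection(unsel.index)
        lost = all_mutants.difference(present)
        if len(lost):
            dropouts.append(pd.DataFrame({"strain": strain, "mutant_id": lost}))
        scored = zscore_classify(
            enrichment_scores(sel.loc[present], unsel.loc[present]),
            high_cut=high_cut, low_cut=low_cut,
        )
        scored.insert(0, "strain", strain)
        frames.append(scored.reset_index(names="mutant_id"))
        by_strain_sel[strain] = sel

    comparisons: dict[str, StrainComparison] = {}
    for i, sa in enumerate(strains):
        for sb in strains[i + 1:]:
            comparisons[f"{sa}_vs_{sb}"] = compare_strains(
                by_strain_sel[sa], by_strain_sel[sb], ci_level=ci_level
            )
    return {
        "scores": pd.concat(frames, ignore_index=True),
        "comparisons": comparisons,
        "dropouts": (
            pd.concat(dropouts, ignore_index=True)
            if dropouts else pd.DataFrame(columns=["strain", "mutant_id"])
        ),
    }
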