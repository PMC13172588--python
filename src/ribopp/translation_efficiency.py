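"""Translation-efficiency (TE) analysis from paired RNA-seq / Ribo-seq counts.

TE for a gene in one (condition, replicate) is the ratio of its ribosome
footprint (RPF) abundance to its mRNA abundance, each expressed as counts
per million after adding a pseudocount:

    TE_g = CPM_rpf(g) / CPM_rna(g)

Differential TE between two conditions is tested per gene on per-replicate
log2 TE with Welch's t-test, and classified against the thresholds
|log2FC| > 1.5 and p < 0.05 (raw p): ``up``, ``down`` or ``ns``. The sign
convention is treated minus control, so translational repression in the
treated condition is negative.

Also provided: the dual-luciferase reporter TE formula and per-fraction
polysome mRNA distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountsExperiment",
    "compute_te",
    "differential_te",
    "reporter_te",
    "polysome_distribution",
]

ASSAYS = ("rna", "rpf")


@dataclass
class CountsExperiment:
    """Gene x sample integer counts with sample metadata.

    ``counts``: DataFrame indexed by gene id, columns are sample ids.
    ``metadata``: DataFrame indexed by sample id with columns
    ``assay`` (rna|rpf), ``condition``, ``replicate``. Every
    (condition, replicate) pair must have exactly one rna and one rpf
    sample.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("gene ids must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        bad = set(self.metadata["assay"]) - set(ASSAYS)
        if bad:
            raise ValueError(f"unknown assay labels: {sorted(bad)}")
        meta = self.metadata.loc[list(self.counts.columns)]
        pairs = meta.groupby(["condition", "replicate"])["assay"]
        for (cond, rep), assays in pairs:
            if sorted(assays) != ["rna", "rpf"]:
                raise ValueError(
                    f"condition {cond!r} replicate {rep!r} lacks a matched rna/rpf pair"
                )

    @property
    def conditions(self) -> list[str]:
        return sorted(self.metadata["condition"].unique())

    def samples(self, assay: str, condition: str) -> pd.DataFrame:
        m = self.metadata
        sel = m[(m["assay"] == assay) & (m["condition"] == condition)]
        return sel.sort_values("replicate")


def _cpm(counts: pd.Series, pseudocount: float) -> pd.Series:
    adj = counts.astype(float) + pseudocount
    return adj / adj.sum() * 1e6


def compute_te(experiment: CountsExperiment, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene TE for every (condition, replicate).

    Returns a DataFrame indexed by gene with MultiIndex columns
    (condition, replicate). The pseudocount (default 1) keeps TE finite
    and strictly positive; CPM normalization makes TE invariant to global
    per-library depth rescaling.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    cols = {}
    for cond in experiment.conditions:
        rna = experiment.samples("rna", cond)
        rpf = experiment.samples("rpf", cond)
        rna_by_rep = dict(zip(rna["replicate"], rna.index))
        for rep, rpf_sample in zip(rpf["replicate"], rpf.index):
            if rep not in rna_by_rep:
                raise ValueError(f"missing rna partner for {cond!r} replicate {rep!r}")
            cpm_rpf = _cpm(experiment.counts[rpf_sample], pseudocount)
            cpm_rna = _cpm(experiment.counts[rna_by_rep[rep]], pseudocount)
            cols[(cond, rep)] = cpm_rpf / cpm_rna
    te = pd.DataFrame(cols)
    te.columns = pd.MultiIndex.from_tuples(te.columns, names=["condition", "replicate"])
    return te


def min_count_mask(
    experiment: CountsExperiment, min_mean_rna: float = 5.0
) -> pd.Series:
    """Boolean per gene: mean raw RNA count across all rna samples >= threshold."""
    rna_samples = experiment.metadata.index[experiment.metadata["assay"] == "rna"]
    return experiment.counts[list(rna_samples)].mean(axis=1) >= min_mean_rna


def differential_te(
    te: pd.DataFrame,
    control: str,
    treated: str,
    lfc_threshold: float = 1.5,
    alpha: float = 0.05,
    tested: pd.Series | None = None,
    test: str = "student",
) -> pd.DataFrame:
    """Differential TE per gene between two conditions.

    ``te`` is the output of :func:`compute_te`. Per gene:
    log2FC = mean log2 TE(treated) - mean log2 TE(control); p from a
    two-sample t-test on per-replicate log2 TE values; class ``up`` if
    log2FC > lfc_threshold and p < alpha, ``down`` if
    log2FC < -lfc_threshold and p < alpha, else ``ns``.

    ``test`` selects the per-gene test: ``"student"`` (pooled variance,
    default — under the TE null both conditions share a variance and the
    pooled test holds its nominal size down to very few replicates) or
    ``"welch"`` (unequal variances; note that the Welch-Satterthwaite df
    approximation is markedly conservative at 3 replicates per group).

    ``tested`` is an optional boolean Series (e.g. a minimum-count filter);
    genes marked False keep their log2FC but get p = NaN and class ``ns``.
    With a single replicate per condition the test is impossible: p is NaN
    and every class is forced ``ns`` with a warning.
    """
    if lfc_threshold <= 0 or not 0 < alpha < 1:
        raise ValueError("thresholds must be positive (and alpha in (0,1))")
    if test not in {"student", "welch"}:
        raise ValueError(f"unknown test {test!r}")
    for cond in (control, treated):
        if cond not in te.columns.get_level_values("condition"):
            raise ValueError(f"condition {cond!r} not present in TE table")

    log_c = np.log2(te[control].to_numpy())
    log_t = np.log2(te[treated].to_numpy())
    lfc = log_t.mean(axis=1) - log_c.mean(axis=1)

    single_rep = log_c.shape[1] < 2 or log_t.shape[1] < 2
    if single_rep:
        warnings.warn(
            "single replicate in a condition: p-values unavailable, all classes 'ns'",
            stacklevel=2,
        )
        pvals = np.full(len(te), np.nan)
    else:
        pvals = stats.ttest_ind(log_t, log_c, axis=1, equal_var=(test == "student")).pvalue

    result = pd.DataFrame(
        {
            "mean_log2_te_control": log_c.mean(axis=1),
            "mean_log2_te_treated": log_t.mean(axis=1),
            "log2fc": lfc,
            "p_value": pvals,
            "tested": True,
        },
        index=te.index,
    )
    if tested is not None:
        excluded = ~tested.reindex(te.index, fill_value=False)
        result.loc[excluded, "p_value"] = np.nan
        result.loc[excluded, "tested"] = False

    sig = result["p_value"] < alpha  # NaN compares False
    result["class"] = "ns"
    result.loc[sig & (result["log2fc"] > lfc_threshold), "class"] = "up"
    result.loc[sig & (result["log2fc"] < -lfc_threshold), "class"] = "down"
    return result


def reporter_te(
    fluc_activity: float,
    rluc_activity: float,
    fluc_mrna: float,
    rluc_mrna: float,
) -> float:
    """Dual-luciferase reporter TE.

    Reporter protein yield (firefly/renilla luminescence) divided by the
    corresponding relative mRNA abundance:
    ``(fluc_activity / rluc_activity) / (fluc_mrna / rluc_mrna)``.
    """
    vals = (fluc_activity, rluc_activity, fluc_mrna, rluc_mrna)
    if any(v <= 0 for v in vals):
        raise ValueError("all reporter measurements must be strictly positive")
    return (fluc_activity / rluc_activity) / (fluc_mrna / rluc_mrna)


def polysome_distribution(amounts: "np.typing.ArrayLike") -> np.ndarray:
    """Relative mRNA distribution across polysome-gradient fractions.

    Normalizes per-fraction relative quantities to proportions summing to
    one, preserving fraction order.
    """
    a = np.asarray(amounts, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise ValueError("amounts must be a non-empty 1-D vector")
    if (a < 0).any():
        raise ValueError("fraction amounts must be non-negative")
    total = a.sum()
    if total == 0:
        raise ValueError("all-zero fraction vector")
    return a / total
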