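"""Concordance of reconstructed regulons with condition-specific expression.

The validation design mirrors carbon-source shift experiments: cells grown on
each test sugar are compared against a reference sugar (ribose in the
Thermotoga experiments), expression is on the log2 scale, replicates are
averaged, and a gene counts as induced when its linear fold change strictly
exceeds a cutoff (default 2).  Regulon-level concordance is formalised as an
upper-tail hypergeometric enrichment of the induced set within each regulon,
with Benjamini-Hochberg correction across the regulons tested in one run.

Missing genes (e.g. probes absent from an array design) are first-class: they
are carried through as 'missing' and reported per regulon, never silently
dropped or imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionMatrix:
    """Gene-by-sample log2 expression with replicate structure.

    ``data`` columns are samples named ``<condition>_<replicate>``;
    ``replicates`` maps each condition to its column names.
    """

    data: pd.DataFrame
    replicates: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.replicates:
            reps: dict[str, list[str]] = {}
            for col in self.data.columns:
                cond = col.rsplit("_", 1)[0]
                reps.setdefault(cond, []).append(col)
            self.replicates = reps
        for cond, cols in self.replicates.items():
            missing = set(cols) - set(self.data.columns)
            if missing:
                raise ValueError(f"condition {cond}: unknown columns {sorted(missing)}")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            # NaN marks a missing probe; infinities are a data error
            arr = self.data.to_numpy(dtype=float)
            if np.isinf(arr).any():
                raise ValueError("expression matrix contains infinite values")

    @property
    def conditions(self) -> list[str]:
        return list(self.replicates)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    def condition_mean(self, condition: str, how: str = "mean") -> pd.Series:
        if condition not in self.replicates:
            raise KeyError(f"unknown condition {condition!r}")
        sub = self.data[self.replicates[condition]]
        return sub.median(axis=1) if how == "median" else sub.mean(axis=1)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t")


def fold_change(
    matrix: ExpressionMatrix,
    condition: str,
    reference: str,
    how: str = "mean",
) -> pd.DataFrame:
    """Per-gene fold change of ``condition`` over ``reference``.

    Replicates are combined by the mean of log2 values (``how='median'`` for
    the median).  Returns a frame with columns ``log2fc`` and ``fc``; genes
    missing in either condition get NaN in both.
    """
    log2fc = matrix.condition_mean(condition, how) - matrix.condition_mean(
        reference, how
    )
    return pd.DataFrame({"log2fc": log2fc, "fc": np.exp2(log2fc)})


def classify_induction(
    fc_table: pd.DataFrame, threshold_fold: float = 2.0
) -> pd.Series:
    """Label each gene induced / not-induced / missing.

    Induction requires fold change strictly greater than ``threshold_fold``
    (a gene at exactly the cutoff is not induced).
    """
    fc = fc_table["fc"]
    labels = pd.Series("not-induced", index=fc.index, dtype=object)
    labels[fc > threshold_fold] = "induced"
    labels[fc.isna()] = "missing"
    return labels


def regulon_enrichment(
    regulon_genes: dict[str, set[str] | list[str]],
    induced: set[str] | list[str],
    universe: set[str] | list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of the induced set in each regulon.

    p is the upper tail P(X >= overlap) for drawing ``len(induced & universe)``
    genes from a universe containing the regulon; q is Benjamini-Hochberg
    across the regulons tested in this call.  Regulon genes outside the
    universe (unmeasured) are reported in ``n_missing`` and excluded from the
    test.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    induced = set(induced) & universe
    rows = []
    for name, genes in regulon_genes.items():
        genes = set(genes)
        measured = genes & universe
        overlap = measured & induced
        M, n, N, k = len(universe), len(measured), len(induced), len(overlap)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append(
            {
                "regulon": name,
                "n_genes": len(genes),
                "n_measured": n,
                "n_missing": len(genes - universe),
                "n_induced": k,
                "p": p,
            }
        )
    df = pd.DataFrame(rows).set_index("regulon")
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df["significant"] = df["q"] < alpha
    return df


def regulon_report(
    regulon_genes: dict[str, set[str] | list[str]],
    fc_table: pd.DataFrame,
    threshold_fold: float = 2.0,
) -> pd.DataFrame:
    """Per-regulon concordance report: counts, median FC, enrichment p/q."""
    labels = classify_induction(fc_table, threshold_fold)
    universe = set(fc_table.index[fc_table["fc"].notna()])
    induced = set(labels.index[labels == "induced"])
    enr = regulon_enrichment(regulon_genes, induced, universe)
    med = []
    for name, genes in regulon_genes.items():
        measured = [g for g in genes if g in universe]
        med.append(float(fc_table.loc[measured, "fc"].median()) if measured else np.nan)
    enr["median_fc"] = med
    return enr
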