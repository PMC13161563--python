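"""Expression-restoration concordance between two differential-expression runs.

Given DE tables for treated-vs-healthy and untreated-vs-healthy
comparisons, the restoration analysis intersects the genes significant in
both, measures the Pearson correlation of their log2 fold changes, and
counts genes whose change reverses direction — a negative correlation with
many reversed genes means treatment shifted the disease transcriptome
toward the healthy reference.

Input tables follow the standard DE-tool export layout (gene_id,
log2FoldChange, pvalue, padj); the DE model fit itself happens upstream
and is consumed as-is.  The default significance criterion is the
adjusted p-value; raw p is available behind a flag.  Genes with a missing
effect or p-value are dropped from the shared set with a tally, and genes
with a log2 fold change of exactly zero are neither concordant nor
reversed — they are counted separately.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RestorationResult",
    "read_de_table",
    "shared_significant",
    "restoration",
    "write_shared_table",
]

REQUIRED_COLUMNS = ("gene_id", "log2FoldChange", "pvalue", "padj")


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Load a DE table (TSV with gene_id, log2FoldChange, pvalue, padj)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ("gene_id", "log2FoldChange") if c not in df.columns]
    if missing:
        raise ValueError(f"DE table {path} lacks required columns {missing}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].head().tolist()
        raise ValueError(f"duplicate gene_ids in {path}: {dups} ...")
    return df.set_index("gene_id")


def _prepare(table: pd.DataFrame) -> pd.DataFrame:
    if isinstance(table.index, pd.RangeIndex) and "gene_id" in table.columns:
        table = table.set_index("gene_id")
    return table


def _significant_ids(
    table: pd.DataFrame, alpha: float, criterion: str
) -> tuple[pd.Index, int]:
    """(significant gene ids, number dropped for NA effect/criterion)."""
    if criterion not in ("padj", "pvalue"):
        raise ValueError("criterion must be 'padj' or 'pvalue'")
    if criterion not in table.columns:
        raise ValueError(f"DE table lacks the {criterion!r} column")
    ok = table["log2FoldChange"].notna() & table[criterion].notna()
    n_dropped = int((~ok).sum())
    sig = table.index[ok & (table[criterion] < alpha)]
    return sig, n_dropped


def shared_significant(
    table_treated: pd.DataFrame,
    table_untreated: pd.DataFrame,
    alpha: float = 0.05,
    criterion: str = "padj",
) -> pd.Index:
    """Genes significant under the chosen criterion in BOTH tables."""
    a = _prepare(table_treated)
    b = _prepare(table_untreated)
    sig_a, _ = _significant_ids(a, alpha, criterion)
    sig_b, _ = _significant_ids(b, alpha, criterion)
    return sig_a.intersection(sig_b).sort_values()


@dataclass
class RestorationResult:
    n_shared_significant: int
    pearson_r: float  # nan when undefined
    p_of_r: float
    n_reversed: int
    reversed_gene_ids: tuple[str, ...]
    n_zero_effect: int
    n_dropped_na: int
    r_defined: bool
    alpha: float
    criterion: str
    shared: Optional[pd.DataFrame] = None  # gene_id, log2fc_treated, log2fc_untreated, reversed

    def to_dict(self) -> dict:
        return {
            "n_shared_significant": self.n_shared_significant,
            "pearson_r": None if math.isnan(self.pearson_r) else round(self.pearson_r, 6),
            "p_of_r": None if math.isnan(self.p_of_r) else float(self.p_of_r),
            "n_reversed": self.n_reversed,
            "reversed_gene_ids": list(self.reversed_gene_ids),
            "n_zero_effect": self.n_zero_effect,
            "n_dropped_na": self.n_dropped_na,
            "r_defined": self.r_defined,
            "alpha": self.alpha,
            "criterion": self.criterion,
        }

    def to_json(self, path: Optional[str | Path] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def restoration(
    table_treated: pd.DataFrame,
    table_untreated: pd.DataFrame,
    alpha: float = 0.05,
    criterion: str = "padj",
) -> RestorationResult:
    """Concordance of expression changes over the co-significant gene set.

    ``pearson_r`` correlates (log2fc_treated, log2fc_untreated) pairs of
    genes significant in both comparisons; it is flagged undefined for
    fewer than 3 shared genes or zero-variance effect vectors.
    ``n_reversed`` counts genes whose fold change flips sign between the
    comparisons (an independent per-gene sign test, not derived from r).
    """
    a = _prepare(table_treated)
    b = _prepare(table_untreated)
    sig_a, drop_a = _significant_ids(a, alpha, criterion)
    sig_b, drop_b = _significant_ids(b, alpha, criterion)
    shared_ids = sig_a.intersection(sig_b).sort_values()
    fc_a = a.loc[shared_ids, "log2FoldChange"].to_numpy(float)
    fc_b = b.loc[shared_ids, "log2FoldChange"].to_numpy(float)

    sign_product = np.sign(fc_a) * np.sign(fc_b)
    reversed_mask = sign_product < 0
    zero_mask = (fc_a == 0) | (fc_b == 0)
    reversed_ids = tuple(shared_ids[reversed_mask])

    r, p = float("nan"), float("nan")
    r_defined = False
    if len(shared_ids) >= 3 and np.std(fc_a) > 0 and np.std(fc_b) > 0:
        r, p = stats.pearsonr(fc_a, fc_b)
        r, p = float(r), float(p)
        r_defined = True

    shared_df = pd.DataFrame(
        {
            "gene_id": shared_ids,
            "log2fc_treated": fc_a,
            "log2fc_untreated": fc_b,
            "reversed": reversed_mask,
        }
    )
    return RestorationResult(
        n_shared_significant=len(shared_ids),
        pearson_r=r,
        p_of_r=p,
        n_reversed=int(reversed_mask.sum()),
        reversed_gene_ids=reversed_ids,
        n_zero_effect=int(zero_mask.sum()),
        n_dropped_na=drop_a + drop_b,
        r_defined=r_defined,
        alpha=alpha,
        criterion=criterion,
        shared=shared_df,
    )


def write_shared_table(
    result: RestorationResult, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        if result.shared is not None:
            result.shared.to_csv(fh, sep="\t", index=False)
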