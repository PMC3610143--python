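"""Relative qPCR quantification by the 2^-ddCt method.

Technical replicates are averaged to one Ct per sample and gene; each
sample's target Ct is normalized to a reference (housekeeping) gene,
dCt = Ct_target - Ct_reference; the between-group difference
ddCt = mean dCt(group A) - mean dCt(group B) gives the expression ratio
of A over B as 2^-ddCt.  Group means are compared with a two-sided Welch
t-test on per-sample dCt values (the safe default at the n = 3 biological
replicates typical of validation panels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["sample_id", "group", "gene_id", "replicate", "ct"]


@dataclass(frozen=True)
class RelativeExpression:
    gene_id: str
    reference_gene: str
    group_a: str
    group_b: str
    mean_dct_a: float
    mean_dct_b: float
    ddct: float
    ratio: float          # 2^-ddCt, expression of group_a relative to group_b
    se: float             # SE of ddCt over biological replicates
    p_value: float        # Welch t-test on per-sample dCt


def read_ct_tsv(path) -> pd.DataFrame:
    """Long-format Ct table: sample_id, group, gene_id, replicate, ct."""
    df = pd.read_csv(path, sep="\t", comment=None)
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df[CT_COLUMNS]


def _per_sample_dct(table: pd.DataFrame, target: str, reference: str) -> pd.DataFrame:
    mean_ct = (table.groupby(["sample_id", "group", "gene_id"])["ct"]
               .mean().reset_index())
    wide = mean_ct.pivot_table(index=["sample_id", "group"], columns="gene_id",
                               values="ct").reset_index()
    for gene in (target, reference):
        if gene not in wide.columns or wide[gene].isna().any():
            bad = (wide.loc[wide[gene].isna(), "sample_id"].tolist()
                   if gene in wide.columns else wide["sample_id"].tolist())
            raise ValueError(f"samples missing Ct for {gene}: {bad}")
    wide["dct"] = wide[target] - wide[reference]
    return wide[["sample_id", "group", "dct"]]


def delta_delta_ct(
    table: pd.DataFrame,
    target: str,
    reference: str,
    group_a: str,
    group_b: str,
) -> RelativeExpression:
    """Relative expression of ``target`` in group_a vs group_b."""
    dct = _per_sample_dct(table, target, reference)
    a = dct.loc[dct["group"] == group_a, "dct"].to_numpy()
    b = dct.loc[dct["group"] == group_b, "dct"].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"no samples for group {group_a if len(a) == 0 else group_b}")
    ddct = float(a.mean() - b.mean())
    se = float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))) \
        if min(len(a), len(b)) > 1 else float("nan")
    if min(len(a), len(b)) > 1:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    else:
        p = float("nan")
    return RelativeExpression(
        gene_id=target, reference_gene=reference,
        group_a=group_a, group_b=group_b,
        mean_dct_a=float(a.mean()), mean_dct_b=float(b.mean()),
        ddct=ddct, ratio=float(2.0 ** -ddct), se=se, p_value=p,
    )


def validation_table(
    table: pd.DataFrame,
    targets: list[str],
    reference: str,
    group_a: str,
    group_b: str,
    dge_ratios: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-gene qPCR ratios, optionally side by side with DGE TPM ratios
    for concordance checks."""
    rows = []
    for gene in targets:
        r = delta_delta_ct(table, gene, reference, group_a, group_b)
        row = {
            "gene_id": gene, "ddct": r.ddct, "qpcr_ratio": r.ratio,
            "se": r.se, "p_value": r.p_value,
        }
        if dge_ratios is not None:
            row["dge_tpm_ratio"] = dge_ratios.get(gene, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)
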