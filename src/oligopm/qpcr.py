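"""Relative standard-curve qPCR quantification.

Each gene's dilution series of genomic DNA yields a straight line
``Ct = slope · log10(quantity) + intercept``; amplification efficiency is
``10^(−1/slope) − 1`` (slope −3.3219 ⇔ 100 % efficiency, i.e. perfect
doubling per cycle).  Unknown samples are interpolated on that line and
target quantities are divided by the reference gene's quantity (SCR1 by
default), so the arbitrary unit of the DNA standards cancels.  An
optional one-way ANOVA + Tukey HSD compares normalized ratios between
sample groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

REFERENCE_GENE = "SCR1"

CT_COLUMNS = ("sample_id", "gene_id", "role", "log10_quantity", "replicate", "ct")


@dataclass(frozen=True)
class DilutionPoint:
    """One standard: log10 input quantity (arbitrary units) and its Ct."""

    log10_quantity: float
    ct: float

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValidationError(f"Ct must be positive, got {self.ct}")


@dataclass
class StandardCurve:
    gene_id: str
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency; 1.0 means doubling every cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def valid(self) -> bool:
        return self.slope < 0


def fit_standard_curve(
    points: Sequence[DilutionPoint], gene_id: str = ""
) -> StandardCurve:
    """Least-squares line through a dilution series.

    Raises on fewer than 3 distinct dilution levels; a non-negative slope
    is kept but flagged (``curve.valid``) with a warning.
    """
    x = np.array([p.log10_quantity for p in points], dtype=float)
    y = np.array([p.ct for p in points], dtype=float)
    if np.unique(x).size < 3:
        raise ValidationError(
            f"standard curve for {gene_id or 'gene'!r} needs >= 3 distinct "
            f"dilutions, got {np.unique(x).size}"
        )
    res = stats.linregress(x, y)
    curve = StandardCurve(
        gene_id=gene_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
    if not curve.valid:
        import warnings

        warnings.warn(
            f"standard curve for {gene_id!r} has non-negative slope "
            f"{curve.slope:.3f}; quantities will be unreliable",
            stacklevel=2,
        )
    return curve


def quantify(curve: StandardCurve, ct: float) -> float:
    """Interpolate a quantity (arbitrary units) from a Ct value."""
    if not curve.valid:
        raise ValidationError(
            f"cannot quantify on invalid curve for {curve.gene_id!r} "
            f"(slope {curve.slope:.3f})"
        )
    return float(10.0 ** ((ct - curve.intercept) / curve.slope))


@dataclass
class NormalizedExpression:
    """Target quantity over reference quantity for one sample."""

    sample_id: str
    target_gene: str
    quantity_target: float
    quantity_reference: float

    @property
    def ratio(self) -> float:
        return self.quantity_target / self.quantity_reference


def normalize_expression(
    target_ct: float,
    reference_ct: float,
    target_curve: StandardCurve,
    reference_curve: StandardCurve,
    sample_id: str = "",
) -> NormalizedExpression:
    return NormalizedExpression(
        sample_id=sample_id,
        target_gene=target_curve.gene_id,
        quantity_target=quantify(target_curve, target_ct),
        quantity_reference=quantify(reference_curve, reference_ct),
    )


# ---------------------------------------------------------------------------
# Table-level pipeline

def read_ct_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = set(CT_COLUMNS) - {"log10_quantity"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"Ct table {path!r} missing columns {sorted(required - set(df.columns))}"
        )
    return df


def process_ct_table(
    df: pd.DataFrame,
    reference_gene: str = REFERENCE_GENE,
    average_replicates: bool = True,
) -> tuple[pd.DataFrame, dict[str, StandardCurve]]:
    """Fit per-gene standard curves and normalize every unknown sample.

    Replicate Ct values are averaged before interpolation by default
    (set ``average_replicates=False`` for per-replicate quantification).
    Returns (expression table, fitted curves).  The expression table has
    one row per sample × target gene (× replicate when not averaging)
    with target/reference quantities and their ratio.
    """
    curves: dict[str, StandardCurve] = {}
    for gene, grp in df[df["role"] == "standard"].groupby("gene_id"):
        pts = [
            DilutionPoint(float(r["log10_quantity"]), float(r["ct"]))
            for _, r in grp.iterrows()
        ]
        curves[str(gene)] = fit_standard_curve(pts, gene_id=str(gene))
    if reference_gene not in curves:
        raise ValidationError(
            f"no standard series for reference gene {reference_gene!r}"
        )

    unknowns = df[df["role"] == "unknown"].copy()
    if unknowns.empty:
        raise ValidationError("Ct table contains no unknown samples")
    group_cols = ["sample_id", "gene_id"]
    if not average_replicates:
        group_cols.append("replicate")
    cts = unknowns.groupby(group_cols, sort=False)["ct"].mean().reset_index()

    ref = cts[cts["gene_id"] == reference_gene].set_index(
        [c for c in group_cols if c != "gene_id"]
    )["ct"]
    rows = []
    for _, row in cts[cts["gene_id"] != reference_gene].iterrows():
        key = (
            row["sample_id"]
            if average_replicates
            else (row["sample_id"], row["replicate"])
        )
        if key not in ref.index:
            raise ValidationError(
                f"sample {row['sample_id']!r} lacks reference-gene Ct"
            )
        gene = str(row["gene_id"])
        ne = normalize_expression(
            float(row["ct"]),
            float(ref.loc[key]),
            curves[gene],
            curves[reference_gene],
            sample_id=str(row["sample_id"]),
        )
        out = {
            "sample_id": ne.sample_id,
            "target_gene": ne.target_gene,
            "quantity_target": ne.quantity_target,
            "quantity_reference": ne.quantity_reference,
            "ratio": ne.ratio,
        }
        if not average_replicates:
            out["replicate"] = row["replicate"]
        rows.append(out)
    return pd.DataFrame(rows), curves


def summarize_replicates(expression: pd.DataFrame) -> pd.DataFrame:
    """Per sample × gene mean and sd of ratios (for per-replicate tables)."""
    return (
        expression.groupby(["sample_id", "target_gene"])["ratio"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )


def compare_groups(
    expression: pd.DataFrame, group_col: str = "group", value_col: str = "ratio"
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA plus Tukey HSD on normalized ratios across groups.

    Off-the-shelf statistics layered on top of the quantification; returns
    (F statistic, p-value, Tukey table).
    """
    groups = [g[value_col].to_numpy() for _, g in expression.groupby(group_col)]
    if len(groups) < 2:
        raise ValidationError("group comparison needs at least 2 groups")
    f_stat, p_value = stats.f_oneway(*groups)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tuk = pairwise_tukeyhsd(
        expression[value_col].to_numpy(), expression[group_col].to_numpy()
    )
    table = pd.DataFrame(
        tuk.summary().data[1:], columns=tuk.summary().data[0]
    )
    return float(f_stat), float(p_value), table
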