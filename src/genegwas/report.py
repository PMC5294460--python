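"""Publication-style outputs: Q-Q and Manhattan data, hit tables, plots.

The data tables are the contract; plot rendering is best-effort and a
backend failure never fails the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .containers import DegenerateInputError, logger
from .genemap import IN_GENE, GeneModel, nearest_gene
from .genetest import GeneTestResult
from .mlm import SnpTestResult

__all__ = [
    "QqData",
    "ManhattanData",
    "make_qq",
    "make_manhattan",
    "make_hit_tables",
    "write_table",
    "read_table",
    "plot_qq",
    "plot_manhattan",
]

#: median of the 1-df chi-square distribution, the denominator of lambda_GC
_CHI2_1_MEDIAN = float(scipy.stats.chi2.ppf(0.5, df=1))


@dataclass
class QqData:
    """Sorted observed vs expected -log10 p plus the inflation factor."""

    observed: np.ndarray  # -log10 p, ascending
    expected: np.ndarray  # -log10((i - 0.5)/m), ascending
    lambda_gc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"expected": self.expected, "observed": self.observed})


@dataclass
class ManhattanData:
    """Per test unit: chromosome, cumulative position, -log10 p."""

    table: pd.DataFrame  # columns: id, chrom, pos_bp, cum_pos, neglog10p
    thresholds: dict[str, float]
    chrom_offsets: dict[str, int]


def make_qq(p_values: Sequence[float] | np.ndarray) -> QqData:
    """Q-Q data for a vector of p-values in (0, 1].

    ``lambda_gc`` is the median of the implied 1-df chi-square statistics
    divided by the null median (~0.4549); values near 1 indicate a
    well-calibrated scan.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise DegenerateInputError("no p-values supplied")
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DegenerateInputError("p-values must lie in (0, 1]")
    m = p.size
    observed = np.sort(-np.log10(p))
    expected = np.sort(-np.log10((np.arange(1, m + 1) - 0.5) / m))
    chi2_obs = scipy.stats.chi2.isf(p, df=1)
    lam = float(np.median(chi2_obs) / _CHI2_1_MEDIAN)
    return QqData(observed=observed, expected=expected, lambda_gc=lam)


def make_manhattan(
    units: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
) -> ManhattanData:
    """Cumulative-coordinate Manhattan data.

    ``units`` needs columns ``id``, ``chrom``, ``pos_bp``, ``p_value``
    (genes enter with their interval midpoint as ``pos_bp``). Chromosomes
    are laid out in natural-sort order with a fixed offset each; the
    result is independent of input row order.
    """
    required = {"id", "chrom", "pos_bp", "p_value"}
    missing = required - set(units.columns)
    if missing:
        raise DegenerateInputError(f"missing Manhattan columns: {sorted(missing)}")
    df = units.copy()
    df["chrom"] = df["chrom"].astype(str)

    def _chrom_key(c: str):
        return (0, int(c)) if c.isdigit() else (1, c)

    chroms = sorted(df["chrom"].unique(), key=_chrom_key)
    offsets: dict[str, int] = {}
    offset = 0
    for c in chroms:
        offsets[c] = offset
        offset += int(df.loc[df["chrom"] == c, "pos_bp"].max()) + 1
    df["cum_pos"] = df["pos_bp"].astype(np.int64) + df["chrom"].map(offsets).astype(np.int64)
    df["neglog10p"] = -np.log10(df["p_value"].astype(float))
    df = df.sort_values(["cum_pos"], kind="stable").reset_index(drop=True)
    return ManhattanData(
        table=df[["id", "chrom", "pos_bp", "cum_pos", "neglog10p"]],
        thresholds=dict(thresholds or {}),
        chrom_offsets=offsets,
    )


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

def _fmt_p(p: float) -> str:
    return f"{p:.2E}"


def make_hit_tables(
    snp_results: Sequence[SnpTestResult],
    gene_results: Sequence[GeneTestResult],
    snp_threshold: float,
    gene_threshold: float,
    genes: Sequence[GeneModel] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Significant-hit tables for the SNP-level and gene-level scans.

    Rows are kept on strict inequality (``p < threshold``). The SNP table
    carries nearest-gene annotation ("in" for SNPs inside a gene body)
    when a gene list is supplied; p-values are formatted in scientific
    notation with two decimals and MAF with four.
    """
    snp_rows = []
    for r in snp_results:
        if not (r.p_value < snp_threshold):
            continue
        gene, dist = (None, None) if genes is None else nearest_gene(r.chrom, r.pos_bp, genes)
        snp_rows.append(
            {
                "SNP": r.snp_id,
                "BTA": r.chrom,
                "Position": r.pos_bp,
                "P value": _fmt_p(r.p_value),
                "MAF": f"{r.maf:.4f}",
                "Nearest Gene Name": "" if gene is None else (gene.symbol or gene.gene_id),
                "Distance": "" if dist is None else (IN_GENE if dist == IN_GENE else str(dist)),
            }
        )
    snp_table = pd.DataFrame(
        snp_rows,
        columns=["SNP", "BTA", "Position", "P value", "MAF", "Nearest Gene Name", "Distance"],
    )

    gene_rows = [
        {
            "Ensembl ID": r.gene_id,
            "Gene symbol": r.symbol,
            "BTA": r.chrom,
            "Start(bp)": r.start_bp,
            "End(bp)": r.end_bp,
            "K": r.k,
            "Chi2": f"{r.chi2_stat:.4f}",
            "P value": _fmt_p(r.gene_p),
        }
        for r in gene_results
        if r.gene_p < gene_threshold
    ]
    gene_table = pd.DataFrame(
        gene_rows,
        columns=["Ensembl ID", "Gene symbol", "BTA", "Start(bp)", "End(bp)", "K", "Chi2", "P value"],
    )
    return snp_table, gene_table


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


# ---------------------------------------------------------------------------
# optional plots
# ---------------------------------------------------------------------------

def plot_qq(qq: QqData, path) -> bool:
    """Render a Q-Q plot; returns False (without raising) if the plotting
    backend is unavailable."""
    try:
        import matplotlib

        matplotlib.use("Agg", force=True)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(qq.expected, qq.observed, ".", ms=3)
        lim = max(qq.expected.max(), qq.observed.max())
        ax.plot([0, lim], [0, lim], "r-", lw=1)
        ax.set_xlabel("expected -log10(p)")
        ax.set_ylabel("observed -log10(p)")
        ax.set_title(f"lambda_GC = {qq.lambda_gc:.3f}")
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)
        return True
    except Exception as exc:  # plotting is best-effort by design
        logger.warning("plot_qq failed: %s", exc)
        return False


def plot_manhattan(data: ManhattanData, path) -> bool:
    """Render a Manhattan plot; returns False on backend failure."""
    try:
        import matplotlib

        matplotlib.use("Agg", force=True)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 3))
        for i, (c, sub) in enumerate(data.table.groupby("chrom", sort=False)):
            ax.plot(sub["cum_pos"], sub["neglog10p"], ".", ms=2,
                    color=["#1f77b4", "#ff7f0e"][i % 2])
        for name, thr in data.thresholds.items():
            ax.axhline(-np.log10(thr), color="red", lw=1, ls="--", label=name)
        if data.thresholds:
            ax.legend(fontsize=7)
        ax.set_xlabel("genomic position")
        ax.set_ylabel("-log10(p)")
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)
        return True
    except Exception as exc:
        logger.warning("plot_manhattan failed: %s", exc)
        return False
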