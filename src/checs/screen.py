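"""Scoring of the sorted-screen count data.

The chain implemented here turns a guides x samples count matrix into a
ranked gene table:

1. per-lane normalisation — each guide's count divided by the lane's total
   library-matching reads;
2. per-replicate enrichment ratio — normalised mCherry+ abundance over
   normalised mCherry- abundance, with a fold floor of 1e-3 when the
   numerator count is zero (completely depleted guide) and a symmetric cap
   of 1e3 when the denominator count is zero;
3. average enrichment score (AES) — geometric mean of the replicate ratios;
4. gene score — sum (default; mean switchable) of AES over the gene's
   guides, reported on the natural-log scale;
5. significance — a one-sided Poisson test per guide and replicate, with
   the expected positive-population count taken from the negative
   population's frequency, combined across all of a gene's guide x
   replicate tests with Fisher's method (-2 sum ln p ~ chi^2 with 2k df)
   and Bonferroni-corrected over the genes tested.

Guides in the positive population come from cells that stayed
reporter-positive, so enrichment (AES > 1, log gene score > 0) marks genes
whose knockdown impairs silencing, i.e. positive regulators of the
effector's activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError, SchemaError
from .manifest import LibraryManifest
from .quant import CountMatrix, sample_name

log = logging.getLogger(__name__)

DEFAULT_FLOOR = 1e-3
DEFAULT_CAP = 1e3
#: Poisson rate floor used when the reference (neg) count is zero
LAMBDA_FLOOR = 0.5
#: smallest P-value reported by the Poisson test (guards log-scale underflow)
P_UNDERFLOW = 1e-300

GENE_TABLE_COLUMNS = [
    "gene_id", "n_guides", "gene_score", "log_gene_score",
    "fisher_statistic", "fisher_df", "combined_p", "bonferroni_p",
    "neg_log10_p", "rank", "direction",
]


def normalize_counts(counts: CountMatrix) -> pd.DataFrame:
    """Per-lane fractions: count / total library-matching reads in the lane.

    Unmatched reads are excluded from the denominator by construction (the
    matrix only holds library-matching reads).
    """
    totals = counts.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise DataError(f"sample(s) with zero matched reads: {list(zero.index)}")
    return counts.counts / totals


def enrichment_scores(
    norm: pd.DataFrame,
    counts: CountMatrix | None = None,
    floor: float = DEFAULT_FLOOR,
    cap: float = DEFAULT_CAP,
) -> pd.DataFrame:
    """Per-replicate pos/neg ratios and the average enrichment score.

    The floor/cap rule is keyed on raw counts: a replicate ratio whose
    positive-population *count* is zero is set to ``floor`` (complete
    depletion); a zero negative-population count sets the ratio to ``cap``.
    ``counts`` defaults to treating zero normalised abundance as zero count.

    Returns a frame indexed by guide_id with columns ``ratio_rep<k>``,
    ``aes``, ``n_floored``, ``n_capped``.
    """
    if floor <= 0 or cap <= 0:
        raise ParameterError("floor and cap must be positive")
    reps = sorted({int(c.split("_")[0][3:]) for c in norm.columns})
    out = pd.DataFrame(index=norm.index)
    n_floored = np.zeros(len(norm), dtype=int)
    n_capped = np.zeros(len(norm), dtype=int)
    raw = counts.counts if counts is not None else norm
    for r in reps:
        pos_name, neg_name = sample_name(r, "pos"), sample_name(r, "neg")
        for name in (pos_name, neg_name):
            if name not in norm.columns:
                raise SchemaError(f"replicate {r} missing sample {name!r}")
        pos, neg = norm[pos_name].to_numpy(), norm[neg_name].to_numpy()
        zero_num = raw[pos_name].to_numpy() == 0
        zero_den = raw[neg_name].to_numpy() == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = pos / neg
        ratio[zero_num] = floor          # depleted: 0 reads in mCherry+
        ratio[zero_den & ~zero_num] = cap
        out[f"ratio_rep{r}"] = ratio
        n_floored += zero_num
        n_capped += zero_den & ~zero_num
    ratio_cols = [c for c in out.columns if c.startswith("ratio_")]
    out["aes"] = np.exp(np.log(out[ratio_cols]).mean(axis=1))
    out["n_floored"] = n_floored
    out["n_capped"] = n_capped
    if n_floored.any() or n_capped.any():
        log.info(
            "enrichment floor applied to %d guide-replicates, cap to %d",
            int(n_floored.sum()), int(n_capped.sum()),
        )
    return out


def gene_scores(
    enrich: pd.DataFrame,
    manifest: LibraryManifest,
    mode: str = "sum",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarise AES per gene; controls are reported separately.

    ``mode='sum'`` adds the AES of a gene's guides (default); ``'mean'``
    averages them — the two differ by ln(n_guides) on the log scale and can
    reorder genes with unequal guide counts.

    Returns ``(genes, controls)``: genes has gene_id, n_guides, gene_score,
    log_gene_score; controls carries the per-control-guide AES.
    """
    if mode not in ("sum", "mean"):
        raise ParameterError(f"gene_score_mode {mode!r} not 'sum'/'mean'")
    gene_of = manifest.gene_of()
    missing = enrich.index.difference(gene_of.index)
    if len(missing):
        raise DataError(f"guide(s) absent from manifest: {list(missing[:5])}")
    is_ctrl = manifest.frame.set_index("guide_id")["is_control"].astype(bool)
    aes = enrich["aes"]
    ctrl_mask = is_ctrl.reindex(enrich.index).to_numpy()
    controls = pd.DataFrame({"aes": aes[ctrl_mask]})
    target = aes[~ctrl_mask]
    grouped = target.groupby(gene_of.reindex(target.index))
    agg = grouped.sum() if mode == "sum" else grouped.mean()
    genes = pd.DataFrame({
        "gene_id": agg.index,
        "n_guides": grouped.size().to_numpy(),
        "gene_score": agg.to_numpy(),
    })
    genes["log_gene_score"] = np.log(genes["gene_score"])
    return genes.reset_index(drop=True), controls


def poisson_pvalues(counts: CountMatrix) -> pd.DataFrame:
    """One-sided (enrichment) Poisson P-values per guide and replicate.

    For guide *i* in replicate *r* the expected positive-population count is
    ``lambda = neg_i / neg_total * pos_total``; the P-value is the Poisson
    upper tail P(X >= observed pos count).  A zero reference count floors
    lambda at 0.5 so the P-value stays positive.
    """
    arr = counts.counts.to_numpy()
    if (arr < 0).any():
        raise DataError("negative count")
    out = pd.DataFrame(index=counts.counts.index)
    for r in counts.replicates:
        pos = counts.column(r, "pos").to_numpy(float)
        neg = counts.column(r, "neg").to_numpy(float)
        lam = neg / neg.sum() * pos.sum()
        lam[neg == 0] = np.maximum(lam[neg == 0], LAMBDA_FLOOR)
        # sf(obs - 1) = P(X >= obs); obs = 0 gives exactly 1.  The survival
        # function underflows to 0 for extreme enrichment; clip to keep
        # P-values in (0, 1] for the downstream log transform.
        out[f"p_rep{r}"] = np.clip(stats.poisson.sf(pos - 1, lam), P_UNDERFLOW, 1.0)
    return out


def fisher_combine(pvalues) -> tuple[float, int, float]:
    """Fisher's method: statistic -2 sum ln p, df = 2k, chi^2 upper tail."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ParameterError("no P-values to combine")
    if (p <= 0).any() or (p > 1).any():
        raise ParameterError("P-values must lie in (0, 1]")
    statistic = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return statistic, df, float(stats.chi2.sf(statistic, df))


def gene_pvalues(
    pois: pd.DataFrame, manifest: LibraryManifest
) -> pd.DataFrame:
    """Combine each gene's guide x replicate P-values; Bonferroni-correct.

    All of a gene's per-guide, per-replicate Poisson P-values enter one
    Fisher combination (k = n_guides x n_replicates).  Controls are
    excluded; the Bonferroni factor m is the number of genes actually
    scored.
    """
    gene_of = manifest.gene_of()
    missing = pois.index.difference(gene_of.index)
    if len(missing):
        raise DataError(f"guide(s) absent from manifest: {list(missing[:5])}")
    is_ctrl = manifest.frame.set_index("guide_id")["is_control"].astype(bool)
    target = pois.loc[~is_ctrl.reindex(pois.index).to_numpy()]
    rows = []
    for gene, block in target.groupby(gene_of.reindex(target.index)):
        vals = block.to_numpy().ravel()
        if vals.size == 0:
            log.warning("gene %s has zero guides; excluded", gene)
            continue
        statistic, df, p = fisher_combine(vals)
        rows.append((gene, statistic, df, max(p, P_UNDERFLOW)))
    out = pd.DataFrame(rows, columns=["gene_id", "fisher_statistic", "fisher_df", "combined_p"])
    m = len(out)
    out["bonferroni_p"] = np.minimum(1.0, out["combined_p"] * m)
    return out


def rank_genes(scores: pd.DataFrame, pvalues: pd.DataFrame) -> pd.DataFrame:
    """Merge scores with significance and rank genes.

    Sorted by log gene score descending; ties broken by smaller combined P,
    then gene id.  ``direction`` is 'positive' for log score > 0 (gene
    supports silencing) and 'negative' otherwise.  ``neg_log10_p`` is the
    plotting significance (-log10 combined P).
    """
    sa, sb = set(scores["gene_id"]), set(pvalues["gene_id"])
    if sa != sb:
        raise SchemaError(
            f"gene sets differ: only-in-scores={sorted(sa - sb)[:5]}, "
            f"only-in-pvalues={sorted(sb - sa)[:5]}"
        )
    table = scores.merge(pvalues, on="gene_id")
    table["neg_log10_p"] = -np.log10(table["combined_p"])
    table = table.sort_values(
        ["log_gene_score", "combined_p", "gene_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["direction"] = np.where(table["log_gene_score"] > 0, "positive", "negative")
    return table[GENE_TABLE_COLUMNS]


# -- model / results objects ------------------------------------------------

@dataclass
class ScreenModel:
    """Sorted-screen scoring model over a count matrix and its manifest.

    ``fit()`` runs the full chain (normalise, enrich, gene scores, Poisson +
    Fisher + Bonferroni significance, ranking) and returns
    :class:`ScreenResults`.
    """

    counts: CountMatrix
    manifest: LibraryManifest
    floor: float = DEFAULT_FLOOR
    cap: float = DEFAULT_CAP
    gene_score_mode: str = "sum"

    @classmethod
    def from_files(cls, counts_path, manifest_path, **kwargs) -> "ScreenModel":
        from .manifest import read_manifest
        from .quant import read_counts

        return cls(read_counts(counts_path), read_manifest(manifest_path), **kwargs)

    def fit(self) -> "ScreenResults":
        self.counts.check_guides(self.manifest)
        norm = normalize_counts(self.counts)
        enrich = enrichment_scores(norm, self.counts, floor=self.floor, cap=self.cap)
        genes, controls = gene_scores(enrich, self.manifest, mode=self.gene_score_mode)
        pois = poisson_pvalues(self.counts)
        pvals = gene_pvalues(pois, self.manifest)
        table = rank_genes(genes, pvals)
        return ScreenResults(
            model=self, normalized=norm, guide_table=enrich.join(pois),
            control_table=controls, gene_table=table,
        )


@dataclass
class ScreenResults:
    """Fitted screen scores: per-guide and ranked per-gene tables."""

    model: ScreenModel
    normalized: pd.DataFrame = field(repr=False)
    guide_table: pd.DataFrame = field(repr=False)
    control_table: pd.DataFrame = field(repr=False)
    gene_table: pd.DataFrame = field(repr=False)

    def top_genes(self, n: int = 10, direction: str | None = "positive") -> pd.DataFrame:
        t = self.gene_table
        if direction is not None:
            t = t[t["direction"] == direction]
        return t.head(n)

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.gene_table[self.gene_table["bonferroni_p"] <= alpha]

    def summary(self, n: int = 10) -> str:
        t = self.gene_table
        lines = [
            "Sorted-screen gene ranking",
            f"  genes scored: {len(t)}   guides: {len(self.guide_table)} "
            f"(+{len(self.control_table)} controls)",
            f"  Bonferroni-significant at 0.05: {len(self.significant())}",
            f"  gene score mode: {self.model.gene_score_mode}, "
            f"floor {self.model.floor:g}, cap {self.model.cap:g}",
            "",
            self.top_genes(n, direction=None).to_string(
                index=False,
                formatters={
                    "gene_score": "{:.3g}".format,
                    "log_gene_score": "{:.3f}".format,
                    "fisher_statistic": "{:.1f}".format,
                    "combined_p": "{:.3g}".format,
                    "bonferroni_p": "{:.3g}".format,
                    "neg_log10_p": "{:.2f}".format,
                },
            ),
        ]
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        """Write gene_scores.tsv and guide_scores.tsv."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.gene_table.to_csv(out / "gene_scores.tsv", sep="\t", index=False)
        self.guide_table.rename_axis("guide_id").to_csv(
            out / "guide_scores.tsv", sep="\t"
        )
        self.control_table.rename_axis("guide_id").to_csv(
            out / "control_scores.tsv", sep="\t"
        )

    def plot_ranking(self, ax=None, max_spot: float = 120.0):
        """Rank-vs-log-score scatter; spot size encodes -log10 P."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.gene_table
        size = t["neg_log10_p"].clip(upper=50) / 50 * max_spot + 4
        colors = np.where(t["direction"] == "positive", "tab:blue", "tab:red")
        ax.scatter(t["rank"], t["log_gene_score"], s=size, c=colors, alpha=0.6,
                   linewidths=0)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("gene rank")
        ax.set_ylabel("ln gene score")
        return ax
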