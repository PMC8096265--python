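"""Guide-library manifests.

A pooled RNAi screen is read out through a catalogue of shRNA constructs,
each identified by the 22-nt guide strand that ends up in the sequencing
read.  The manifest maps every guide to its target gene and flags the
neutral control constructs that are spiked into the library.

The reference library emulated throughout the package is a chromatin-focused
collection of 5451 target shRNAs covering 1010 genes at 4-6 guides per gene,
plus 8 control shRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

GUIDE_LENGTH = 22
#: reserved gene_id for control shRNAs; distinct from any target gene
CONTROL_GENE = "CONTROL"

MANIFEST_COLUMNS = ["guide_id", "gene_id", "guide_seq", "is_control"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class LibraryManifest:
    """Immutable guide catalogue.

    Parameters
    ----------
    frame : pandas.DataFrame
        Columns ``guide_id``, ``gene_id``, ``guide_seq`` (22-nt, ACGT),
        ``is_control`` (bool).  Validated on construction.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"manifest missing columns: {missing}")
        if df["guide_id"].duplicated().any():
            dup = df.loc[df["guide_id"].duplicated(), "guide_id"].iloc[0]
            raise FormatError(f"duplicate guide_id in manifest: {dup!r}")
        if df["guide_seq"].duplicated().any():
            dup = df.loc[df["guide_seq"].duplicated(), "guide_seq"].iloc[0]
            raise FormatError(f"duplicate guide sequence in manifest: {dup!r}")
        bad = ~df["guide_seq"].str.fullmatch(f"[ACGT]{{{GUIDE_LENGTH}}}")
        if bad.any():
            offender = df.loc[bad, "guide_id"].iloc[0]
            raise FormatError(
                f"guide {offender!r}: sequence must be {GUIDE_LENGTH} nt over ACGT"
            )
        is_ctrl = df["is_control"].astype(bool)
        if (is_ctrl & (df["gene_id"] != CONTROL_GENE)).any():
            raise FormatError(f"control guides must use gene_id {CONTROL_GENE!r}")
        if (~is_ctrl & (df["gene_id"] == CONTROL_GENE)).any():
            raise FormatError(f"gene_id {CONTROL_GENE!r} is reserved for controls")

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def guide_ids(self) -> pd.Index:
        return pd.Index(self.frame["guide_id"])

    @property
    def n_genes(self) -> int:
        """Number of distinct target genes (controls excluded)."""
        return self.frame.loc[~self.frame["is_control"].astype(bool), "gene_id"].nunique()

    @property
    def n_controls(self) -> int:
        return int(self.frame["is_control"].astype(bool).sum())

    @property
    def targets(self) -> pd.DataFrame:
        """Rows for target (non-control) guides."""
        return self.frame[~self.frame["is_control"].astype(bool)]

    def gene_of(self) -> pd.Series:
        """guide_id -> gene_id mapping as a Series."""
        return self.frame.set_index("guide_id")["gene_id"]

    def seq_index(self) -> dict[str, str]:
        """guide_seq -> guide_id lookup used by the exact-match counter."""
        return dict(zip(self.frame["guide_seq"], self.frame["guide_id"]))


def build_manifest(
    n_genes: int,
    guides_per_gene: tuple[int, int] = (4, 6),
    n_controls: int = 8,
    seed: int = 0,
    n_guides_total: int | None = None,
) -> LibraryManifest:
    """Generate a random guide library.

    Per-gene guide counts are drawn uniformly from ``guides_per_gene``
    (inclusive).  If ``n_guides_total`` is given, the draw is rebalanced
    (deterministically under ``seed``) so the target guides sum exactly to
    that total — required to reproduce a library whose total is not the
    mean of the range, e.g. 5451 guides over 1010 genes.

    Guide sequences are unique random 22-mers over ACGT.
    """
    lo, hi = guides_per_gene
    if lo > hi:
        raise ParameterError(f"guides_per_gene range inverted: {lo} > {hi}")
    if n_genes < 1 or lo < 1:
        raise ParameterError("n_genes and guides_per_gene bounds must be >= 1")
    if n_controls < 0:
        raise ParameterError("n_controls must be >= 0")
    rng = np.random.default_rng(seed)

    counts = rng.integers(lo, hi + 1, size=n_genes)
    if n_guides_total is not None:
        if not n_genes * lo <= n_guides_total <= n_genes * hi:
            raise ParameterError(
                f"n_guides_total={n_guides_total} infeasible for "
                f"{n_genes} genes at {lo}-{hi} guides each"
            )
        # rebalance: bump random genes that still have slack
        while counts.sum() != n_guides_total:
            delta = int(np.sign(n_guides_total - counts.sum()))
            room = np.flatnonzero(counts < hi if delta > 0 else counts > lo)
            counts[rng.choice(room)] += delta

    total = int(counts.sum()) + n_controls
    seqs = _unique_kmers(total, rng)

    gene_ids = [f"gene{g + 1:04d}" for g in range(n_genes)]
    rows: list[tuple[str, str, str, bool]] = []
    i = 0
    for g, c in zip(gene_ids, counts):
        for j in range(int(c)):
            rows.append((f"{g}_sh{j + 1}", g, seqs[i], False))
            i += 1
    for j in range(n_controls):
        rows.append((f"ctrl_sh{j + 1}", CONTROL_GENE, seqs[i], True))
        i += 1
    frame = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return LibraryManifest(frame)


def default_manifest(seed: int = 0) -> LibraryManifest:
    """The reference library: 5451 target shRNAs / 1010 genes + 8 controls."""
    return build_manifest(
        n_genes=1010, guides_per_gene=(4, 6), n_controls=8, seed=seed,
        n_guides_total=5451,
    )


def library_coverage(
    n_cells: float, transduction_efficiency: float, n_guides: int
) -> float:
    """Expected transduced cells per guide at single-copy infection.

    At 30e6 cells, 10% efficiency and a 5459-guide library this exceeds 500
    cells per shRNA, the representation floor used when scaling the screen.
    """
    if not 0 < transduction_efficiency <= 1:
        raise ParameterError("transduction_efficiency must be in (0, 1]")
    if n_guides < 1:
        raise ParameterError("n_guides must be >= 1")
    return n_cells * transduction_efficiency / n_guides


def _unique_kmers(n: int, rng: np.random.Generator, k: int = GUIDE_LENGTH) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = _BASES[rng.integers(0, 4, size=(n - len(out), k))]
        for row in block:
            s = "".join(row)
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


# -- IO ---------------------------------------------------------------------

def read_manifest(path) -> LibraryManifest:
    """Read a tab-separated manifest (guide_id, gene_id, guide_seq, is_control)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing manifest columns {missing}")
    flags = df["is_control"].str.strip().str.lower()
    valid = {"0": False, "1": True, "false": False, "true": True}
    if not flags.isin(valid).all():
        bad = df.loc[~flags.isin(valid), "is_control"].iloc[0]
        raise FormatError(f"{path}: is_control value {bad!r} not 0/1/true/false")
    df["is_control"] = flags.map(valid)
    return LibraryManifest(df[MANIFEST_COLUMNS])


def write_manifest(manifest: LibraryManifest, path) -> None:
    out = manifest.frame.copy()
    out["is_control"] = out["is_control"].astype(bool).astype(int)
    out.to_csv(path, sep="\t", index=False)
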