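"""Guide quantification: exact 22-mer matching of FASTQ reads, count matrices.

Reads from the sorted screen are 150 bp and contain the 22-nt guide strand
of one shRNA.  A read is assigned to a guide when a 22-nt window of the read
equals the guide sequence exactly; no mismatches are tolerated (guides are
distinguishable at 22 nt and the screen quantification is defined on exact
matching reads).  Reads matching no guide are tallied as unmatched and are
excluded from downstream normalisation denominators.

Sample columns follow the naming convention ``rep<k>_<pos|neg>`` for the
mCherry-positive / mCherry-negative sorted populations of replicate *k*.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .errors import DataError, FormatError, ParameterError
from .manifest import GUIDE_LENGTH, LibraryManifest

log = logging.getLogger(__name__)

_SAMPLE_RE = re.compile(r"^rep(\d+)_(pos|neg)$")
_UNMATCHED_PREFIX = "#unmatched"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def sample_name(replicate: int, population: str) -> str:
    return f"rep{replicate}_{population}"


def parse_sample_name(name: str) -> tuple[int, str]:
    """Split ``rep<k>_<pos|neg>`` into (replicate, population)."""
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise FormatError(
            f"sample column {name!r} does not match 'rep<k>_<pos|neg>'"
        )
    return int(m.group(1)), m.group(2)


@dataclass
class CountMatrix:
    """Integer read counts, guides x samples, plus per-sample unmatched tallies.

    ``counts`` is indexed by guide_id with one column per sample; values are
    non-negative integers.  ``unmatched`` maps sample id to the number of
    reads that matched no guide.
    """

    counts: pd.DataFrame
    unmatched: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicated guide row: {dup!r}")
        if self.counts.columns.duplicated().any():
            raise FormatError("duplicated sample columns")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise DataError("negative count in matrix")
        self.counts = self.counts.astype(np.int64)
        self.counts.index.name = "guide_id"
        self.unmatched = {c: int(self.unmatched.get(c, 0)) for c in self.counts.columns}

    @property
    def samples(self) -> list[tuple[str, int, str]]:
        """(sample_id, replicate, population) for every column."""
        return [(c, *parse_sample_name(c)) for c in self.counts.columns]

    @property
    def replicates(self) -> list[int]:
        return sorted({r for _, r, _ in self.samples})

    def column(self, replicate: int, population: str) -> pd.Series:
        return self.counts[sample_name(replicate, population)]

    def check_guides(self, manifest: LibraryManifest) -> None:
        extra = self.counts.index.difference(manifest.guide_ids)
        if len(extra):
            raise DataError(f"guides absent from manifest: {list(extra[:5])}")


# -- exact-match counting ---------------------------------------------------

def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def count_guides(
    fastq,
    manifest: LibraryManifest,
    offset: int | str = "scan",
    orientation: str = "forward",
) -> tuple[pd.Series, int]:
    """Count exact guide matches in one FASTQ sample.

    Parameters
    ----------
    fastq : path or iterable of str
        FASTQ file (gzip ok) or an iterable of read sequences.
    offset : int or "scan"
        Fixed 0-based position of the guide window, or "scan" to slide the
        window across the read; the leftmost matching window wins and each
        read increments at most one guide.
    orientation : {"forward", "both"}
        With "both", the reverse complement of the read is scanned when the
        forward orientation finds no match.

    Returns
    -------
    (counts, unmatched) : counts is a Series over all manifest guide ids.
    """
    if orientation not in ("forward", "both"):
        raise ParameterError(f"orientation {orientation!r} not 'forward'/'both'")
    if offset != "scan" and (not isinstance(offset, int) or offset < 0):
        raise ParameterError(f"offset must be a non-negative int or 'scan', got {offset!r}")
    lookup = manifest.seq_index()
    counts: dict[str, int] = dict.fromkeys(manifest.frame["guide_id"], 0)
    unmatched = 0
    n_short = 0
    k = GUIDE_LENGTH

    for seq in _iter_sequences(fastq):
        if len(seq) < k:
            n_short += 1
            unmatched += 1
            continue
        gid = _match_one(seq, lookup, offset, k)
        if gid is None and orientation == "both":
            gid = _match_one(revcomp(seq), lookup, offset, k)
        if gid is None:
            unmatched += 1
        else:
            counts[gid] += 1
    if n_short:
        log.warning("%d reads shorter than %d nt counted as unmatched", n_short, k)
    return pd.Series(counts, name="count"), unmatched


def _match_one(seq: str, lookup: dict[str, str], offset, k: int):
    if offset == "scan":
        for i in range(len(seq) - k + 1):
            gid = lookup.get(seq[i : i + k])
            if gid is not None:
                return gid
        return None
    if len(seq) < offset + k:
        return None
    return lookup.get(seq[offset : offset + k])


def _iter_sequences(fastq):
    if isinstance(fastq, (str, bytes)) or hasattr(fastq, "__fspath__"):
        with pysam.FastxFile(str(fastq)) as fh:
            for entry in fh:
                yield entry.sequence.upper()
    else:
        for seq in fastq:
            yield seq.upper()


def count_samples(
    fastq_by_sample: dict[str, object],
    manifest: LibraryManifest,
    offset: int | str = "scan",
    orientation: str = "forward",
) -> CountMatrix:
    """Count several FASTQ samples into one CountMatrix.

    Keys of ``fastq_by_sample`` are sample ids (``rep<k>_<pos|neg>``).
    """
    cols = {}
    unmatched = {}
    for sid, fq in fastq_by_sample.items():
        parse_sample_name(sid)  # validate early
        col, um = count_guides(fq, manifest, offset=offset, orientation=orientation)
        cols[sid] = col
        unmatched[sid] = um
    return CountMatrix(pd.DataFrame(cols), unmatched)


# -- IO ---------------------------------------------------------------------

def write_counts(matrix: CountMatrix, path) -> None:
    """Write the tab-separated count schema (unmatched tallies as # header lines)."""
    with open(path, "w") as fh:
        for sid, um in matrix.unmatched.items():
            fh.write(f"{_UNMATCHED_PREFIX}\t{sid}\t{um}\n")
        matrix.counts.rename_axis("guide_id").to_csv(fh, sep="\t")


def read_counts(path) -> CountMatrix:
    """Read a count matrix written by :func:`write_counts`.

    Raises :class:`FormatError` naming the offending cell for non-integer
    values, duplicated guide rows, or sample columns not matching
    ``rep<k>_<pos|neg>``.
    """
    unmatched: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith(_UNMATCHED_PREFIX):
                break
            _, sid, um = line.rstrip("\n").split("\t")
            unmatched[sid] = int(um)
    # body re-read with pandas; the tally lines are skipped as comments
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "guide_id" not in df.columns:
        raise FormatError(f"{path}: first column must be guide_id")
    df = df.set_index("guide_id")
    for col in df.columns:
        parse_sample_name(col)
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | (converted != converted.round())
        if bad.any():
            guide = df.index[bad][0]
            raise FormatError(
                f"{path}: non-integer count {df.loc[guide, col]!r} "
                f"at guide {guide!r}, sample {col!r}"
            )
        df[col] = converted.astype(np.int64)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicated guide row {dup!r}")
    return CountMatrix(df, unmatched)
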