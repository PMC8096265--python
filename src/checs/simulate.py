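"""Synthetic data generators for every input the pipeline consumes.

The screen generator emulates a FACS-sorted pooled shRNA screen: cells carry
one guide each, a guide's knockdown either lets the cell escape reporter
silencing (stay mCherry-positive) or not, cells are sorted on a latent
reporter value into a positive gate (top 6-8%) and a negative gate (bottom
75-80%), and each sorted population is sequenced to a fixed read depth with
multinomial sampling over the guide frequencies among sorted cells.

Defaults follow the reference screen: a 1010-gene / 5459-shRNA library,
five replicates, gates at 0.07 and 0.775 (midpoints of the quoted sorting
windows), and 3e6 cells per replicate.

Also here: FASTQ emission for the simulated counts (150-nt reads embedding
the 22-nt guide strand), single-site binding titrations, and qPCR Cq tables
with IP / input / IgG / spike-in structure.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParameterError, SchemaError
from .manifest import GUIDE_LENGTH, LibraryManifest, build_manifest
from .quant import CountMatrix, sample_name

# fixed 8-nt vector anchors flanking the guide in emitted reads, so that
# offset-scan matching can be exercised against realistic context
ANCHOR_5P = "TAGTGAAG"
ANCHOR_3P = "TGCCTACT"


@dataclass(frozen=True)
class ScreenSimParams:
    """Study conditions of the simulated sorted screen.

    Escape probabilities are the chance that a cell carrying a given guide
    remains reporter-positive after induction: background guides rarely
    escape; guides against genes required for silencing escape often.
    """

    n_genes: int = 1010
    guides_per_gene: tuple[int, int] = (4, 6)
    n_controls: int = 8
    n_replicates: int = 5
    n_cells: int = 3_000_000
    pos_gate_fraction: float = 0.07
    neg_gate_fraction: float = 0.775
    hit_gene_fraction: float = 0.05
    hit_escape_prob: float = 0.9
    background_escape_prob: float = 0.05
    reads_per_sample: int = 10_000_000
    seed: int = 0
    n_guides_total: int | None = 5451

    def validate(self) -> None:
        for name in ("pos_gate_fraction", "neg_gate_fraction", "hit_gene_fraction",
                     "hit_escape_prob", "background_escape_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.pos_gate_fraction + self.neg_gate_fraction > 1.0:
            raise ParameterError(
                "pos_gate_fraction + neg_gate_fraction exceeds 1: gates overlap"
            )
        for name in ("n_genes", "n_replicates", "n_cells", "reads_per_sample"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be positive")


@dataclass(frozen=True)
class TruthTable:
    """Planted ground truth of a simulated screen."""

    genes: pd.DataFrame   # gene_id, is_hit, escape_prob
    guides: pd.DataFrame  # guide_id, gene_id, escape_prob


#: latent reporter noise scale; escapers score 1 + eps, silenced cells eps,
#: so gates separate the two classes while ties within a class are random
_REPORTER_NOISE_SD = 0.1


def simulate_screen(
    manifest: LibraryManifest, params: ScreenSimParams
) -> tuple[CountMatrix, TruthTable]:
    """Simulate sorted-population read counts with planted hit genes.

    Per replicate: cells draw guides uniformly, escape reporter silencing
    with their guide's probability, and are ranked by a latent reporter
    value (escapers at 1 + eps, silenced at eps).  The positive sample is
    the top ``pos_gate_fraction`` of cells, the negative sample the bottom
    ``neg_gate_fraction``; each sample's reads are multinomial over the
    guide frequencies of its sorted cells.
    """
    params.validate()
    if len(manifest) == 0:
        raise ParameterError("manifest is empty")
    rng = np.random.default_rng(params.seed)
    guide_ids = manifest.frame["guide_id"].to_numpy()
    gene_ids = manifest.frame["gene_id"].to_numpy()
    is_control = manifest.frame["is_control"].to_numpy(bool)
    n_guides = len(guide_ids)

    target_genes = pd.unique(gene_ids[~is_control])
    n_hits = int(round(params.hit_gene_fraction * len(target_genes)))
    hit_genes = set(rng.choice(target_genes, size=n_hits, replace=False)) if n_hits else set()

    escape = np.where(
        np.isin(gene_ids, list(hit_genes)) & ~is_control,
        params.hit_escape_prob,
        params.background_escape_prob,
    )

    n_pos = int(params.pos_gate_fraction * params.n_cells)
    n_neg = int(params.neg_gate_fraction * params.n_cells)
    cols: dict[str, np.ndarray] = {}
    for r in range(1, params.n_replicates + 1):
        g = rng.integers(0, n_guides, size=params.n_cells)
        escaped = rng.random(params.n_cells) < escape[g]
        value = escaped + rng.normal(0.0, _REPORTER_NOISE_SD, size=params.n_cells)
        order = np.argsort(value, kind="stable")
        gate = {
            "pos": g[order[params.n_cells - n_pos:]],
            "neg": g[order[:n_neg]],
        }
        for pop, cells in gate.items():
            freq = np.bincount(cells, minlength=n_guides).astype(float)
            freq /= freq.sum()
            cols[sample_name(r, pop)] = rng.multinomial(params.reads_per_sample, freq)

    counts = CountMatrix(pd.DataFrame(cols, index=pd.Index(guide_ids, name="guide_id")))
    genes = pd.DataFrame({
        "gene_id": target_genes,
        "is_hit": [g in hit_genes for g in target_genes],
        "escape_prob": [
            params.hit_escape_prob if g in hit_genes else params.background_escape_prob
            for g in target_genes
        ],
    })
    guides = pd.DataFrame(
        {"guide_id": guide_ids, "gene_id": gene_ids, "escape_prob": escape}
    )
    return counts, TruthTable(genes=genes, guides=guides)


def simulate_screen_dataset(
    params: ScreenSimParams,
) -> tuple[LibraryManifest, CountMatrix, TruthTable]:
    """Build a manifest from ``params`` and simulate a screen on it."""
    manifest = build_manifest(
        params.n_genes, params.guides_per_gene, params.n_controls,
        seed=params.seed, n_guides_total=params.n_guides_total,
    )
    return (manifest, *simulate_screen(manifest, params))


def null_params(**overrides) -> ScreenSimParams:
    """Study conditions with no planted effects (uniform escape)."""
    return replace(ScreenSimParams(hit_gene_fraction=0.0), **overrides)


# -- FASTQ emission ---------------------------------------------------------

def emit_fastq(
    counts: CountMatrix,
    manifest: LibraryManifest,
    out_dir,
    read_length: int = 150,
    guide_offset: int = 30,
    seed: int = 0,
    gz: bool = False,
) -> dict[str, str]:
    """Write one FASTQ file per sample embedding guide strands in reads.

    Each read is ``read_length`` nt: random filler, an 8-nt fixed vector
    anchor, the 22-nt guide at ``guide_offset``, a second anchor, filler.
    Column sums of ``counts`` give the exact number of reads per sample.
    Returns sample_id -> written path.
    """
    if read_length < guide_offset + GUIDE_LENGTH:
        raise ParameterError(
            f"read_length {read_length} too short for guide at offset {guide_offset}"
        )
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    seqs = manifest.frame.set_index("guide_id")["guide_seq"]
    bases = np.array(list("ACGT"))
    qual = "I" * read_length
    paths: dict[str, str] = {}
    for sid in counts.counts.columns:
        col = counts.counts[sid]
        guide_idx = np.repeat(np.arange(len(col)), col.to_numpy())
        rng.shuffle(guide_idx)
        path = out_dir / f"{sid}.fastq{'.gz' if gz else ''}"
        opener = gzip.open if gz else open
        with opener(path, "wt") as fh:
            for i, gi in enumerate(guide_idx):
                read = _build_read(
                    seqs.iloc[int(gi)], read_length, guide_offset, bases, rng
                )
                fh.write(f"@{sid}_{i}\n{read}\n+\n{qual}\n")
        paths[sid] = str(path)
    return paths


def _build_read(guide_seq, read_length, guide_offset, bases, rng):
    filler = bases[rng.integers(0, 4, size=read_length)]
    read = list(filler)
    a5 = ANCHOR_5P[max(0, len(ANCHOR_5P) - guide_offset):]
    read[guide_offset - len(a5): guide_offset] = list(a5)
    read[guide_offset: guide_offset + GUIDE_LENGTH] = list(guide_seq)
    a3 = ANCHOR_3P[: max(0, read_length - guide_offset - GUIDE_LENGTH)]
    read[guide_offset + GUIDE_LENGTH: guide_offset + GUIDE_LENGTH + len(a3)] = list(a3)
    return "".join(read)


# -- binding titrations -----------------------------------------------------

def binding_signal(conc, kd: float, f: float, bl: float):
    """Single-site equilibrium binding: BL + F * c / (c + K_D)."""
    conc = np.asarray(conc, dtype=float)
    return bl + f * conc / (conc + kd)


def simulate_titration(
    kd: float,
    f: float = 0.10,
    bl: float = 0.05,
    conc_grid=None,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    control_level: float | None = None,
):
    """Simulate fluorescence-anisotropy titrations of a single-site binder.

    ``kd`` is in the same concentration units as ``conc_grid`` (nM
    throughout the package; the reference affinity scale is 82 nM).
    ``control_level`` adds a buffer-only control series at that constant
    signal (plus noise) on the same grid.
    """
    from .binding import TitrationSeries

    if kd <= 0:
        raise ParameterError(f"kd must be > 0, got {kd}")
    if conc_grid is None:
        conc_grid = np.geomspace(1.0, 2000.0, 12)
    conc = np.asarray(conc_grid, dtype=float)
    if (conc < 0).any() or (np.diff(conc) < 0).any():
        raise ParameterError("conc_grid must be non-negative and sorted")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        sig = binding_signal(conc, kd, f, bl) + rng.normal(0, noise_sd, size=len(conc))
        for c, s in zip(conc, sig):
            rows.append((c, s, f"rep{rep}", "measurement"))
    if control_level is not None:
        for rep in range(1, n_replicates + 1):
            sig = control_level + rng.normal(0, noise_sd, size=len(conc))
            for c, s in zip(conc, sig):
                rows.append((c, s, f"rep{rep}", "control"))
    frame = pd.DataFrame(rows, columns=["concentration_nM", "signal", "replicate", "series"])
    return TitrationSeries.from_frame(frame)


# -- qPCR Cq tables ---------------------------------------------------------

CQ_COLUMNS = ["sample_id", "condition", "replicate", "target", "role", "cq"]
CQ_ROLES = ("IP", "input", "IgG", "spike_in")


def simulate_cq(
    design: dict[str, int],
    true_enrichments: dict[str, float],
    efficiency: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    input_fraction: float = 0.1,
    roles=CQ_ROLES,
    target: str = "EF1a_promoter",
    pulldown: float = 0.05,
    igg_pulldown: float = 1e-3,
    base_input_cq: float = 22.0,
    spike_base_input_cq: float = 24.0,
) -> pd.DataFrame:
    """Generate a Cq table whose relative quantification recovers the truth.

    ``design`` maps condition label -> number of replicates;
    ``true_enrichments`` maps condition -> planted fold enrichment.  Cq
    values are constructed on the log-efficiency scale so that percent-input
    with spike-in normalisation returns the planted folds exactly at
    ``noise_sd=0``.  Spike-in rows use role ``spike_in`` with the ``target``
    field naming the compartment (IP or input) of the spike amplicon.
    """
    if efficiency <= 1:
        raise ParameterError(f"efficiency must be > 1, got {efficiency}")
    need = {"IP", "input"}
    if not need <= set(roles):
        raise SchemaError(f"design must include roles {sorted(need)}, got {list(roles)}")
    missing = set(design) - set(true_enrichments)
    if missing:
        raise SchemaError(f"conditions without true_enrichments: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    log_eff = math.log(efficiency)

    def cycles(x: float) -> float:
        return math.log(x) / log_eff

    rows = []
    for cond, n_reps in design.items():
        enr = true_enrichments[cond]
        for rep in range(1, n_reps + 1):
            sid = f"{cond}_r{rep}"
            input_cq = base_input_cq
            adj_input = input_cq - cycles(1.0 / input_fraction)
            ip_cq = adj_input - cycles(pulldown * enr)
            entries = {
                "IP": (target, ip_cq),
                "input": (target, input_cq),
                "IgG": (target, adj_input - cycles(igg_pulldown)),
            }
            for role in roles:
                if role == "spike_in":
                    continue
                t, cq = entries[role]
                rows.append((sid, cond, f"rep{rep}", t, role,
                             cq + rng.normal(0, noise_sd)))
            if "spike_in" in roles:
                sp_input = spike_base_input_cq
                sp_adj = sp_input - cycles(1.0 / input_fraction)
                sp_ip = sp_adj - cycles(pulldown)
                rows.append((sid, cond, f"rep{rep}", "IP", "spike_in",
                             sp_ip + rng.normal(0, noise_sd)))
                rows.append((sid, cond, f"rep{rep}", "input", "spike_in",
                             sp_input + rng.normal(0, noise_sd)))
    return pd.DataFrame(rows, columns=CQ_COLUMNS)
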