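"""Sequence-structure mapping: homolog search, global realignment and
cysteine placement.

For each query protein the pipeline (1) finds a homologous structure
sequence (E-value gate, default E < 1e-4), (2) recomputes the residue
correspondence with a full dynamic-programming alignment, and (3) places
the query's eligible cysteines at the C-alpha coordinates of their aligned
structure residues.  Two mapped cysteines closer than the cutoff (default
8 Angstrom, C-alpha to C-alpha) are judged a probable disulfide; each
participating cysteine is a "hit", counted once regardless of how many
partners it has.

The realignment is a semi-global (free end gap) Needleman-Wunsch/Gotoh
affine-gap alignment authored here, with deterministic traceback
(diagonal, then query-consuming, then target-consuming moves).  The search
step is a BLAST stand-in: Smith-Waterman scores via Biopython with a
Karlin-Altschul style E-value on top; it reproduces the accept/reject
behaviour at the gate, not BLAST's exact E-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .proteome_io import ProteinRecord
from .structure_db import StructureChain

# Gapped BLOSUM62 convention: a gap of length k costs GAP_OPEN + k*GAP_EXTEND.
GAP_OPEN = 11.0
GAP_EXTEND = 1.0
# Karlin-Altschul constants for the internal E-value (gapped BLOSUM62).
LAMBDA = 0.267
KAPPA = 0.041

_BLOSUM = substitution_matrices.load("BLOSUM62")
_MATRIX_ALPHABET = set(_BLOSUM.alphabet)


def _sanitize(seq: str) -> str:
    """Map residues outside the scoring alphabet: U (selenocysteine) scores
    as C, anything else unknown as X."""
    return "".join(
        c if c in _MATRIX_ALPHABET else ("C" if c == "U" else "X") for c in seq
    )


def substitution_score(a: str, b: str) -> float:
    return float(_BLOSUM[_sanitize(a), _sanitize(b)])


@dataclass(frozen=True)
class SearchParams:
    evalue_max: float = 1e-4
    hit_source: str = "internal"  # internal | tabular

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if self.hit_source not in {"internal", "tabular"}:
            raise ValueError(f"unknown hit_source {self.hit_source!r}")


@dataclass(frozen=True)
class Hit:
    target_id: str
    evalue: float
    score: float


@dataclass
class AlignmentResult:
    """Residue correspondence from a pairwise alignment.

    ``pairs`` lists (query 0-based index, target 0-based ordinal) for every
    aligned (match/mismatch) column, strictly increasing in both
    coordinates; ``identity`` is matches over aligned columns.
    """

    query_id: str
    target_id: str
    pairs: tuple[tuple[int, int], ...]
    score: float
    identity: float


@dataclass
class MappingResult:
    """Query cysteines placed in a structure's coordinate frame."""

    query_id: str
    structure_id: str
    chain_id: str
    mapped_cys: list[tuple[int, int, np.ndarray]]  # (query pos, target ordinal, CA)
    unmapped_cys: list[int]
    pair_distances: dict[tuple[int, int], float]
    cutoff: float = 8.0
    hits: set[int] = field(init=False)
    predicted_pairs: set[tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        self.hits, self.predicted_pairs = _proximity(self.pair_distances, self.cutoff)

    @property
    def n_mapped(self) -> int:
        return len(self.mapped_cys)

    @property
    def n_hits(self) -> int:
        return len(self.hits)


# ---------------------------------------------------------------------------
# homolog search
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _BLOSUM
    aligner.mode = "local"
    # Biopython charges open_gap_score for the first gap position, so the
    # open+k*extend convention maps to open+extend for that first position.
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def evalue_from_score(score: float, m: int, n: int) -> float:
    return KAPPA * m * n * math.exp(-LAMBDA * score)


def search_homologs(
    query: ProteinRecord,
    library: Mapping[str, str],
    params: SearchParams | None = None,
    tabular_path: str | Path | None = None,
) -> list[Hit]:
    """Rank library sequences by E-value against a query.

    ``internal`` mode scores every library sequence with Smith-Waterman
    (BLOSUM62, gap open 11 / extend 1) and converts scores to E-values with
    E = K*m*n*exp(-lambda*S).  ``tabular`` mode reads a 12-column
    blast-tabular file instead.  Hits with E-value >= the gate are dropped;
    ties are broken by descending score then lexicographic target id.
    """
    params = params or SearchParams()
    if params.hit_source == "tabular":
        if tabular_path is None:
            raise ValueError("tabular hit source requires tabular_path")
        hits = [
            h for h in read_tabular_hits(tabular_path).get(query.id, [])
            if h.evalue < params.evalue_max
        ]
    else:
        if not library:
            raise ValueError("empty structure-sequence library")
        aligner = _local_aligner()
        qseq = _sanitize(query.sequence)
        hits = []
        for target_id, tseq in library.items():
            s = float(aligner.score(qseq, _sanitize(tseq)))
            e = evalue_from_score(s, len(qseq), len(tseq))
            if e < params.evalue_max:
                hits.append(Hit(target_id=target_id, evalue=e, score=s))
    hits.sort(key=lambda h: (h.evalue, -h.score, h.target_id))
    return hits


TABULAR_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_tabular_hits(path: str | Path) -> dict[str, list[Hit]]:
    """Parse a 12-column blast-tabular (outfmt 6) file into hits per query."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: dict[str, list[Hit]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 12:
            raise ValueError(f"{path.name}:{lineno}: expected 12 columns")
        out.setdefault(fields[0], []).append(
            Hit(target_id=fields[1], evalue=float(fields[10]), score=float(fields[11]))
        )
    return out


def load_library_fasta(path: str | Path) -> dict[str, str]:
    """Structure-sequence library FASTA with ids of the form 'entry_chain'."""
    from Bio import SeqIO

    lib: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        lib[rec.id] = str(rec.seq).upper()
    if not lib:
        raise ValueError(f"no sequences in {path}")
    return lib


# ---------------------------------------------------------------------------
# global realignment (Gotoh affine-gap DP with deterministic traceback)
# ---------------------------------------------------------------------------

_NEG = float("-inf")


def global_realign(
    query_seq: str,
    target_seq: str,
    *,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
    semiglobal: bool = True,
    query_id: str = "",
    target_id: str = "",
) -> AlignmentResult:
    """Optimal global alignment under BLOSUM62 with affine gaps.

    End gaps are free by default (``semiglobal=True``), which avoids
    pathological penalties when the structure covers only a fragment of the
    query; set ``semiglobal=False`` for a strict global alignment.  A gap of
    length k costs ``gap_open + k*gap_extend``.  Traceback ties prefer the
    diagonal move, then the query-consuming (up) move, then the
    target-consuming (left) move.
    """
    if not query_seq or not target_seq:
        raise ValueError("sequences must be non-empty")
    q = _sanitize(query_seq)
    t = _sanitize(target_seq)
    n, m = len(q), len(t)
    open_cost = gap_open + gap_extend

    idx = {c: i for i, c in enumerate(_BLOSUM.alphabet)}
    mat = np.asarray(_BLOSUM)
    qi = [idx[c] for c in q]
    ti = [idx[c] for c in t]
    sub_rows = [mat[a] for a in qi]  # per-query-residue score vectors

    S = [[0.0] * (m + 1) for _ in range(n + 1)]
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in target (consume query)
    Iy = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (consume target)

    if not semiglobal:
        for i in range(1, n + 1):
            Ix[i][0] = S[i][0] = -(gap_open + gap_extend * i)
        for j in range(1, m + 1):
            Iy[0][j] = S[0][j] = -(gap_open + gap_extend * j)

    for i in range(1, n + 1):
        Si_1, Si = S[i - 1], S[i]
        Mi, Ixi, Iyi = M[i], Ix[i], Iy[i]
        Ixi_1 = Ix[i - 1]
        row = sub_rows[i - 1]
        for j in range(1, m + 1):
            Mi[j] = Si_1[j - 1] + row[ti[j - 1]]
            Ixi[j] = max(Si_1[j] - open_cost, Ixi_1[j] - gap_extend)
            Iyi[j] = max(Si[j - 1] - open_cost, Iyi[j - 1] - gap_extend)
            Si[j] = max(Mi[j], Ixi[j], Iyi[j])

    if semiglobal:
        bi, bj, best = n, m, S[n][m]
        for j in range(m - 1, -1, -1):
            if S[n][j] > best:
                bi, bj, best = n, j, S[n][j]
        for i in range(n - 1, -1, -1):
            if S[i][m] > best:
                bi, bj, best = i, m, S[i][m]
    else:
        bi, bj, best = n, m, S[n][m]

    # traceback (recomputing state choices; ties: M, then Ix, then Iy)
    pairs: list[tuple[int, int]] = []
    i, j = bi, bj

    def state_at(i: int, j: int) -> str:
        s = S[i][j]
        if M[i][j] == s:
            return "M"
        if Ix[i][j] == s:
            return "X"
        return "Y"

    state = state_at(i, j) if (i > 0 and j > 0) or not semiglobal else None
    while i > 0 and j > 0:
        if state == "M":
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
            if i == 0 or j == 0:
                break
            state = state_at(i, j)
        elif state == "X":
            # prefer closing the gap (open from S) over extending it
            if S[i - 1][j] - open_cost == Ix[i][j]:
                i -= 1
                if i == 0:
                    break
                state = state_at(i, j)
            else:
                i -= 1
                state = "X"
        else:  # "Y"
            if S[i][j - 1] - open_cost == Iy[i][j]:
                j -= 1
                if j == 0:
                    break
                state = state_at(i, j)
            else:
                j -= 1
                state = "Y"

    pairs.reverse()
    matches = sum(1 for a, b in pairs if q[a] == t[b])
    identity = matches / len(pairs) if pairs else 0.0
    return AlignmentResult(
        query_id=query_id,
        target_id=target_id,
        pairs=tuple(pairs),
        score=float(best),
        identity=identity,
    )


# ---------------------------------------------------------------------------
# cysteine placement and proximity
# ---------------------------------------------------------------------------

def _proximity(
    pair_distances: Mapping[tuple[int, int], float], cutoff: float
) -> tuple[set[int], set[tuple[int, int]]]:
    predicted = {pair for pair, d in pair_distances.items() if d < cutoff}
    hits = {p for pair in predicted for p in pair}
    return hits, predicted


def map_cysteines(
    alignment: AlignmentResult,
    chain: StructureChain,
    eligible_cys: Sequence[int],
    cutoff: float = 8.0,
) -> MappingResult:
    """Place eligible query cysteines at their aligned structure residues.

    A cysteine maps when its query position sits in a match column whose
    target residue has a CA coordinate (the target residue need not be
    cysteine); others are reported unmapped.  All intra-chain pairwise CA
    distances among mapped cysteines are computed.
    """
    if alignment.pairs and max(tj for _, tj in alignment.pairs) >= len(chain.residues):
        raise ValueError(
            f"alignment target ordinals exceed chain length {len(chain.residues)}"
        )
    qmap = {qi: tj for qi, tj in alignment.pairs}
    mapped: list[tuple[int, int, np.ndarray]] = []
    unmapped: list[int] = []
    for pos in eligible_cys:
        tj = qmap.get(pos)
        if tj is None or chain.ca_coords[tj] is None:
            unmapped.append(pos)
        else:
            mapped.append((pos, tj, chain.ca_coords[tj]))
    distances: dict[tuple[int, int], float] = {}
    for (pa, _, ca), (pb, _, cb) in combinations(mapped, 2):
        distances[(pa, pb)] = float(np.linalg.norm(ca - cb))
    return MappingResult(
        query_id=alignment.query_id,
        structure_id=chain.structure_id,
        chain_id=chain.chain_id,
        mapped_cys=mapped,
        unmapped_cys=unmapped,
        pair_distances=distances,
        cutoff=cutoff,
    )


def proximity_hits(
    mapping: MappingResult, cutoff_angstrom: float = 8.0
) -> tuple[int, set[tuple[int, int]]]:
    """Count hit cysteines at an arbitrary cutoff (strict inequality).

    A mapped cysteine is a hit when at least one *other* mapped cysteine
    lies at CA distance < cutoff; it is counted once regardless of partner
    multiplicity.  Returns (hit count, predicted pairs).
    """
    if cutoff_angstrom <= 0:
        raise ValueError("cutoff must be > 0")
    hits, predicted = _proximity(mapping.pair_distances, cutoff_angstrom)
    return len(hits), predicted


def annotate_odd_case(
    mapping: MappingResult,
    chain: StructureChain,
    metal_cutoff: float = 8.0,
    neighbor_radius: float = 10.0,
    buried_min_neighbors: int = 12,
) -> dict[int, str]:
    """Classify mapped non-hit cysteines (the "odd cysteine out" cases).

    A free cysteine is ``metal-proximal`` when its CA lies within
    ``metal_cutoff`` of a HET metal atom, else ``surface-candidate`` when it
    has fewer than ``buried_min_neighbors`` other CA atoms within
    ``neighbor_radius``, else ``buried-unpaired``.  Surface-poised free
    cysteines are candidates for intermolecular disulfides.
    """
    all_ca = np.array([c for c in chain.ca_coords if c is not None])
    labels: dict[int, str] = {}
    for pos, _tj, ca in mapping.mapped_cys:
        if pos in mapping.hits:
            continue
        if any(
            float(np.linalg.norm(ca - mpos)) < metal_cutoff
            for _sym, mpos in chain.metal_sites
        ):
            labels[pos] = "metal-proximal"
            continue
        dists = np.linalg.norm(all_ca - ca, axis=1)
        n_neighbors = int(np.sum(dists < neighbor_radius)) - 1  # exclude self
        labels[pos] = (
            "surface-candidate"
            if n_neighbors < buried_min_neighbors
            else "buried-unpaired"
        )
    return labels
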