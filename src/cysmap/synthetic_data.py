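"""Synthetic proteome/structure bundles with known ground truth.

The generator emulates the inputs of a proteome-wide disulfide survey:

* CA-only structure models built as self-avoiding 3.8-Angstrom random
  walks, with disulfide-paired cysteines steered to a CA-CA separation
  inside [4.0, 6.5] Angstrom (comfortably under the 8 Angstrom criterion)
  and free cysteines kept at least 10 Angstrom from any other cysteine;
* protein sequences derived from each structure's sequence with point
  substitutions at a controlled divergence (planted cysteines preserved,
  substitutions never introduce new cysteines);
* optional signal peptides (secreted fraction), CXXC metal motifs next to
  a Zn site with LINK records, and odd unpaired extra cysteines.

Every random choice flows from a single integer seed; the realized pooled
true disulfide fraction is recorded in the truth object and is the
authoritative value (it can differ from the requested target by
discretization).  Body sequences draw from a cysteine-free background
composition so the only cysteines are the planted ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .filters import predict_signal_peptide
from .proteome_io import ProteinRecord, ProteomeSet, write_fasta
from .structure_db import StructureChain, write_structure

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# Background amino-acid frequencies (Robinson & Robinson style), with
# cysteine removed and the rest renormalized: planted cysteines must be the
# only ones.
_BG_LETTERS = np.array(list("ARNDQEGHILKMFPSTWYV"))
_BG_FREQS = np.array(
    [
        0.078, 0.051, 0.045, 0.054, 0.043, 0.063, 0.074, 0.022, 0.051,
        0.057, 0.090, 0.057, 0.039, 0.052, 0.071, 0.058, 0.013, 0.032,
        0.065,
    ]
)
_BG_FREQS = _BG_FREQS / _BG_FREQS.sum()

STEP = 3.8  # CA-CA virtual bond length, Angstrom
MIN_CLASH = 3.5  # soft self-avoidance floor for non-adjacent CA pairs


class GeometryError(RuntimeError):
    """Raised when a structure's cysteine geometry cannot be satisfied;
    usually the chain is too short for the requested plan."""


@dataclass
class CysPlan:
    """Planted cysteine layout for one structure (0-based positions)."""

    pairs: list[tuple[int, int]] = field(default_factory=list)
    singles: list[int] = field(default_factory=list)
    metal_pairs: list[tuple[int, int]] = field(default_factory=list)  # CXXC, Zn-linked
    link_singles: list[int] = field(default_factory=list)  # LINK'd to a non-Zn metal

    @property
    def all_cys(self) -> list[int]:
        out = [p for pair in self.pairs for p in pair]
        out += self.singles + self.link_singles
        out += [p for pair in self.metal_pairs for p in pair]
        return sorted(out)


@dataclass
class GeneratorParams:
    n_proteins: int = 200
    length_range: tuple[int, int] = (150, 200)
    true_f: float = 0.5
    divergence: float = 0.10
    secreted_fraction: float = 0.20
    metal_motif_fraction: float = 0.10
    odd_cys_fraction: float = 0.10
    pair_ca_range: tuple[float, float] = (4.0, 6.5)
    free_min_sep: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("true_f", "secreted_fraction", "metal_motif_fraction",
                     "odd_cys_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.divergence <= 0.5:
            raise ValueError("divergence must be in [0, 0.5]")
        if self.true_f == 1.0 and self.odd_cys_fraction > 0:
            raise ValueError(
                "true_f=1.0 is infeasible with odd_cys_fraction > 0 "
                "(unpaired extra cysteines lower the realized fraction)"
            )


@dataclass
class ProteinTruth:
    id: str
    structure_id: str
    pairs: list[tuple[int, int]]  # protein coordinates, 0-based
    free_cys: list[int]  # includes any odd extra cysteine
    metal_cys: list[int]  # CXXC positions (spacing-masked downstream)
    secreted: bool
    signal_len: int
    n_substitutions: int


@dataclass
class StructureTruth:
    structure_id: str
    ssbond_pairs: list[tuple[int, int]]  # auth residue numbers (1-based)
    link_cys: list[int]
    metals: list[str]


@dataclass
class SyntheticTruth:
    proteins: dict[str, ProteinTruth]
    structures: dict[str, StructureTruth]
    true_f: float

    def recompute_true_f(self) -> float:
        """Fraction of eligible planted cysteines that sit in pairs."""
        paired = sum(2 * len(p.pairs) for p in self.proteins.values())
        free = sum(len(p.free_cys) for p in self.proteins.values())
        return paired / (paired + free) if (paired + free) else 0.0


@dataclass
class SyntheticBundle:
    proteome: ProteomeSet
    library: dict[str, str]  # "entry_chain" -> structure sequence
    chains: dict[str, StructureChain]  # structure_id -> chain
    truth: SyntheticTruth

    @property
    def structures(self) -> dict[str, dict[str, StructureChain]]:
        return {sid: {ch.chain_id: ch} for sid, ch in self.chains.items()}


# ---------------------------------------------------------------------------
# CA trace generation
# ---------------------------------------------------------------------------

def _random_units(rng: np.random.Generator, k: int) -> np.ndarray:
    v = rng.normal(size=(k, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _try_walk(
    n: int,
    plan: CysPlan,
    rng: np.random.Generator,
    pair_lo: float,
    pair_hi: float,
) -> np.ndarray | None:
    """One attempt at a self-avoiding CA walk satisfying the pair windows."""
    steer_target: dict[int, int] = {}  # second pair member -> first member
    for i, j in plan.pairs:
        a, b = min(i, j), max(i, j)
        steer_target[b] = a

    coords = np.zeros((n, 3))
    active_pair: tuple[int, int] | None = None  # (target residue idx, partner idx)

    for t in range(1, n):
        prev = coords[t - 1]
        # is a pair closure coming up?
        closing = steer_target.get(t)
        approaching = None
        for b, a in steer_target.items():
            if a < t < b:
                approaching = (b, a)
                break

        placed = False
        if closing is not None:
            # exact construction: points at STEP from prev and d* from the
            # anchor form a circle (two-sphere intersection); sample on it
            anchor = coords[closing]
            axis = anchor - prev
            dp = float(np.linalg.norm(axis))
            lo = max(pair_lo + 0.2, dp - STEP + 1e-6)
            hi = min(pair_hi - 0.2, dp + STEP - 1e-6)
            if dp > 1e-9 and lo < hi:
                axis = axis / dp
                # orthonormal frame around the prev->anchor axis
                ref = np.array([1.0, 0.0, 0.0])
                if abs(axis[0]) > 0.9:
                    ref = np.array([0.0, 1.0, 0.0])
                u = np.cross(axis, ref)
                u /= np.linalg.norm(u)
                v = np.cross(axis, u)
                for _ in range(120):
                    d_star = rng.uniform(lo, hi)
                    h = (STEP**2 - d_star**2 + dp**2) / (2 * dp)
                    r2 = STEP**2 - h**2
                    if r2 <= 0:
                        continue
                    phi = rng.uniform(0, 2 * np.pi)
                    cand = prev + h * axis + np.sqrt(r2) * (
                        np.cos(phi) * u + np.sin(phi) * v
                    )
                    if t >= 2 and np.min(
                        np.linalg.norm(coords[: t - 1] - cand, axis=1)
                    ) < MIN_CLASH:
                        continue
                    coords[t] = cand
                    placed = True
                    break
        else:
            for _ in range(120):
                direction = _random_units(rng, 1)[0]
                if approaching is not None:
                    b, a = approaching
                    to_anchor = coords[a] - prev
                    dist = float(np.linalg.norm(to_anchor))
                    reach = (b - t) * STEP
                    # track a corridor: stay near a target radius that
                    # shrinks with the remaining steps, so the walker
                    # neither drifts out of reach nor hovers in the
                    # crowded region around the anchor
                    d_des = max(reach - 8.0, 6.0)
                    w = min(0.8, max(0.0, (dist - d_des) / 10.0))
                    if w > 0 and dist > 1e-9:
                        direction = w * to_anchor / dist + (1 - w) * direction
                        direction /= np.linalg.norm(direction)
                cand = prev + STEP * direction
                if approaching is not None:
                    b, a = approaching
                    # hard reachability guard: keep the anchor within range
                    # of the remaining steps (closing needs dp <= STEP+hi)
                    if np.linalg.norm(cand - coords[a]) > (b - t) * STEP + 6.0:
                        continue
                cand_ok = not (
                    t >= 2
                    and np.min(np.linalg.norm(coords[: t - 1] - cand, axis=1))
                    < MIN_CLASH
                )
                if not cand_ok:
                    continue
                coords[t] = cand
                placed = True
                break
        if not placed:
            return None
    return coords


def _zn_positions(coords: np.ndarray, plan: CysPlan) -> list[np.ndarray]:
    return [
        (coords[i] + coords[j]) / 2.0 + np.array([0.0, 0.0, 0.5])
        for i, j in plan.metal_pairs
    ]


def _geometry_ok(
    coords: np.ndarray,
    plan: CysPlan,
    pair_lo: float,
    pair_hi: float,
    free_min_sep: float,
    metal_clearance: float = 9.0,
) -> bool:
    cys = plan.all_cys
    for i, j in plan.pairs:
        d = np.linalg.norm(coords[i] - coords[j])
        if not pair_lo < d < pair_hi:
            return False
    for s in plan.singles + plan.link_singles:
        others = [c for c in cys if c != s]
        if others and min(
            np.linalg.norm(coords[s] - coords[c]) for c in others
        ) < free_min_sep:
            return False
        for zn in _zn_positions(coords, plan):
            if np.linalg.norm(coords[s] - zn) < metal_clearance:
                return False
    return True


def generate_structure(
    n_residues: int,
    plan: CysPlan,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    sequence: str | None = None,
    structure_id: str = "S000",
    chain_id: str = "A",
    pair_ca_range: tuple[float, float] = (4.0, 6.5),
    free_min_sep: float = 10.0,
    link_metal: str = "CU",
    max_attempts: int = 300,
) -> StructureChain:
    """Build one CA-only chain realizing a cysteine plan.

    Paired cysteine CAs end up inside ``pair_ca_range``; free (single)
    cysteines at least ``free_min_sep`` from every other cysteine CA.
    SSBOND records are attached for planted pairs, LINK records plus HET
    metal sites for metal cases.  Deterministic for a given seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if plan.all_cys and max(plan.all_cys) >= n_residues:
        raise GeometryError("cysteine plan does not fit in the chain")
    if sequence is not None and len(sequence) != n_residues:
        raise ValueError("sequence length does not match n_residues")

    pair_lo, pair_hi = pair_ca_range
    coords = None
    for _ in range(max_attempts):
        c = _try_walk(n_residues, plan, rng, pair_lo, pair_hi)
        if c is not None and _geometry_ok(c, plan, pair_lo, pair_hi, free_min_sep):
            coords = c
            break
    if coords is None:
        raise GeometryError(
            f"could not satisfy cysteine geometry for {structure_id} "
            f"(n={n_residues}); try a longer chain or fewer planted cysteines"
        )

    if sequence is None:
        letters = rng.choice(_BG_LETTERS, size=n_residues, p=_BG_FREQS)
        sequence = "".join(letters)
        seq = list(sequence)
        seq[0] = "M"
        for p in plan.all_cys:
            seq[p] = "C"
        sequence = "".join(seq)
    else:
        for p in plan.all_cys:
            if sequence[p] != "C":
                raise ValueError(f"sequence position {p} must be 'C'")

    residues = [
        (i + 1, "", _ONE_TO_THREE.get(aa, "GLY")) for i, aa in enumerate(sequence)
    ]
    ca_coords: list[np.ndarray | None] = [coords[i] for i in range(n_residues)]

    ssbond_pairs = {(min(i, j) + 1, max(i, j) + 1) for i, j in plan.pairs}
    ssbond_cys = {p for pair in ssbond_pairs for p in pair}
    link_cys = {p + 1 for pair in plan.metal_pairs for p in pair}
    link_cys |= {s + 1 for s in plan.link_singles}

    metal_sites: list[tuple[str, np.ndarray]] = [
        ("ZN", zn) for zn in _zn_positions(coords, plan)
    ]
    for s in plan.link_singles:
        offset = np.array([1.6, 1.6, 0.0])
        metal_sites.append((link_metal.upper(), coords[s] + offset))

    return StructureChain(
        structure_id=structure_id,
        chain_id=chain_id,
        residues=residues,
        ca_coords=ca_coords,
        ssbond_pairs=ssbond_pairs,
        ssbond_cys=ssbond_cys,
        link_cys=link_cys,
        bound_metals={sym for sym, _ in metal_sites},
        metal_sites=metal_sites,
    )


# ---------------------------------------------------------------------------
# sequence-level helpers
# ---------------------------------------------------------------------------

def _sample_background(rng: np.random.Generator, k: int) -> str:
    return "".join(rng.choice(_BG_LETTERS, size=k, p=_BG_FREQS))


def _make_signal_peptide(rng: np.random.Generator) -> str:
    """An N-terminal signal peptide satisfying the heuristic detector:
    charged n-region, 10-residue hydrophobic h-region, A-X-A style
    cleavage site.  Contains no cysteine."""
    hydro = "AILMFVW"
    polar = "STNQ"
    small = "AGSTV"
    n_region = "M" + rng.choice(list("KR")) + "".join(rng.choice(list(polar), size=2))
    h_region = "".join(rng.choice(list(hydro), size=int(rng.integers(10, 12))))
    c_mid = "".join(rng.choice(list(polar), size=int(rng.integers(1, 3))))
    c_region = c_mid + rng.choice(list(small)) + rng.choice(list(polar)) + rng.choice(list(small))
    sp = n_region + h_region + c_region
    score, is_secreted = predict_signal_peptide(sp + "D" * 30)
    assert is_secreted, (sp, score)
    return sp


def _mutate(
    body: str, keep: set[int], divergence: float, rng: np.random.Generator
) -> tuple[str, int]:
    if divergence == 0.0:
        return body, 0
    seq = list(body)
    n_subs = 0
    mask = rng.random(len(seq)) < divergence
    for pos in np.nonzero(mask)[0]:
        if int(pos) in keep or pos == 0:
            continue
        old = seq[pos]
        new = old
        while new == old:
            new = str(rng.choice(_BG_LETTERS, p=_BG_FREQS))
        seq[pos] = new
        n_subs += 1
    return "".join(seq), n_subs


def _plan_layout(
    length: int,
    paired: bool,
    n_extra_singles: int,
    has_metal: bool,
    rng: np.random.Generator,
) -> CysPlan:
    """Place cysteine units with sequence-separation guards: >5 between any
    two planted cysteines (so the spacing mask never touches them, except
    the CXXC motif which is masked by design) and >=30 around singles (so
    the random-walk geometry can hold the 10-Angstrom spatial floor)."""
    units: list[tuple[list[int], bool]] = []  # (offsets, is_single)
    if paired:
        gap = int(rng.integers(8, 26))
        units.append(([0, gap], False))
    else:
        units.append(([0], True))
        units.append(([0], True))
    for _ in range(n_extra_singles):
        units.append(([0], True))
    if has_metal:
        units.append(([0, 3], False))

    for _ in range(2000):
        positions: list[list[int]] = []
        ok = True
        for offsets, _single in units:
            anchor = int(rng.integers(3, length - 4 - max(offsets)))
            positions.append([anchor + o for o in offsets])
        for a in range(len(units)):
            for b in range(a + 1, len(units)):
                sep_needed = 30 if (units[a][1] or units[b][1]) else 7
                if min(
                    abs(x - y) for x in positions[a] for y in positions[b]
                ) < sep_needed:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            plan = CysPlan()
            idx = 0
            if paired:
                plan.pairs.append(tuple(positions[0]))  # type: ignore[arg-type]
                idx = 1
            else:
                plan.singles.extend([positions[0][0], positions[1][0]])
                idx = 2
            for k in range(n_extra_singles):
                plan.singles.append(positions[idx + k][0])
            if has_metal:
                plan.metal_pairs.append(tuple(positions[-1]))  # type: ignore[arg-type]
            return plan
    raise GeometryError(f"could not lay out cysteines in a {length}-residue chain")


# ---------------------------------------------------------------------------
# bundle generation
# ---------------------------------------------------------------------------

def generate_proteome(
    params: GeneratorParams, out_dir: str | Path | None = None
) -> SyntheticBundle:
    """Generate a proteome, its structure library and the ground truth.

    Each protein derives from one generated structure: the structure keeps
    the native sequence (exported to the library FASTA), the protein gets
    point substitutions at the requested divergence.  A deterministic
    number of proteins (round(true_f * n)) carries a disulfide pair; the
    others carry two spatially separated free cysteines.  Optional extras:
    signal peptides, CXXC+Zn metal motifs, odd unpaired cysteines.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_proteins
    n_paired = round(params.true_f * n)

    paired_flags = np.zeros(n, dtype=bool)
    paired_flags[rng.permutation(n)[:n_paired]] = True
    odd_flags = np.zeros(n, dtype=bool)
    odd_flags[rng.permutation(n)[: round(params.odd_cys_fraction * n)]] = True
    metal_flags = np.zeros(n, dtype=bool)
    metal_flags[rng.permutation(n)[: round(params.metal_motif_fraction * n)]] = True
    secreted_flags = np.zeros(n, dtype=bool)
    secreted_flags[rng.permutation(n)[: round(params.secreted_fraction * n)]] = True

    child_seeds = rng.integers(0, 2**31 - 1, size=n)

    records: list[ProteinRecord] = []
    library: dict[str, str] = {}
    chains: dict[str, StructureChain] = {}
    protein_truth: dict[str, ProteinTruth] = {}
    structure_truth: dict[str, StructureTruth] = {}

    for k in range(n):
        sid = f"S{k:03d}"
        pid = f"syn{k:04d}"
        length = int(rng.integers(params.length_range[0], params.length_range[1] + 1))
        plan = _plan_layout(
            length,
            paired=bool(paired_flags[k]),
            n_extra_singles=int(odd_flags[k]),
            has_metal=bool(metal_flags[k]),
            rng=rng,
        )
        chain = generate_structure(
            length,
            plan,
            seed=int(child_seeds[k]),
            structure_id=sid,
            chain_id="A",
            pair_ca_range=params.pair_ca_range,
            free_min_sep=params.free_min_sep,
        )
        body = chain.sequence
        library[f"{sid}_A"] = body
        chains[sid] = chain

        keep = set(plan.all_cys)
        mutated, n_subs = _mutate(body, keep, params.divergence, rng)
        signal = _make_signal_peptide(rng) if secreted_flags[k] else ""
        shift = len(signal)
        sequence = signal + mutated

        records.append(ProteinRecord(id=pid, sequence=sequence, organism="synthetic"))
        protein_truth[pid] = ProteinTruth(
            id=pid,
            structure_id=sid,
            pairs=[(i + shift, j + shift) for i, j in plan.pairs],
            free_cys=[s + shift for s in plan.singles],
            metal_cys=[p + shift for pair in plan.metal_pairs for p in pair],
            secreted=bool(secreted_flags[k]),
            signal_len=shift,
            n_substitutions=n_subs,
        )
        structure_truth[sid] = StructureTruth(
            structure_id=sid,
            ssbond_pairs=sorted(chain.ssbond_pairs),
            link_cys=sorted(chain.link_cys),
            metals=sorted(chain.bound_metals),
        )

    truth = SyntheticTruth(
        proteins=protein_truth, structures=structure_truth, true_f=0.0
    )
    truth.true_f = truth.recompute_true_f()

    proteome = ProteomeSet(
        label=f"synthetic_seed{params.seed}", records=records, source="synthetic"
    )
    bundle = SyntheticBundle(
        proteome=proteome, library=library, chains=chains, truth=truth
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write proteome FASTA, library FASTA, per-structure PDB files and a
    truth TSV under ``out_dir``; returns the paths."""
    out = Path(out_dir)
    (out / "structures").mkdir(parents=True, exist_ok=True)
    paths = {
        "proteome": out / "proteome.fasta",
        "library": out / "library.fasta",
        "structures": out / "structures",
        "truth": out / "truth.tsv",
    }
    write_fasta(bundle.proteome, paths["proteome"])
    with open(paths["library"], "w") as fh:
        for lid in sorted(bundle.library):
            fh.write(f">{lid}\n")
            seq = bundle.library[lid]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    for sid in sorted(bundle.chains):
        write_structure([bundle.chains[sid]], paths["structures"] / f"{sid}.pdb")
    with open(paths["truth"], "w") as fh:
        fh.write(f"# true_f\t{bundle.truth.true_f:.6f}\n")
        fh.write(
            "id\tstructure_id\tpairs\tfree_cys\tmetal_cys\tsecreted\t"
            "signal_len\tn_substitutions\n"
        )
        for p in bundle.truth.proteins.values():
            pairs = ";".join(f"{i}-{j}" for i, j in p.pairs)
            fh.write(
                f"{p.id}\t{p.structure_id}\t{pairs}\t"
                f"{';'.join(map(str, p.free_cys))}\t"
                f"{';'.join(map(str, p.metal_cys))}\t"
                f"{int(p.secreted)}\t{p.signal_len}\t{p.n_substitutions}\n"
            )
    return paths


# ---------------------------------------------------------------------------
# control-structure sets (for f') and parity proteomes
# ---------------------------------------------------------------------------

def generate_control_structures(
    n_entries: int = 20,
    seed: int = 0,
    zn_fraction: float = 0.25,
    link_fraction: float = 0.3,
    length_range: tuple[int, int] = (60, 100),
) -> tuple[list[StructureChain], dict]:
    """Structure entries with planted SSBOND/LINK/Zn content for testing f'.

    Returns the chains plus a truth dict with the expected numerator,
    denominator and ratio under the counting rules (Zn/Fe entries excluded
    wholesale, LINK cysteines excluded from the denominator, SSBOND
    cysteines counted in the numerator).
    """
    rng = np.random.default_rng(seed)
    chains: list[StructureChain] = []
    numer = denom = n_excluded = 0
    for k in range(n_entries):
        length = int(rng.integers(*length_range))
        n_pairs = int(rng.integers(0, 3)) if k > 0 else 1
        n_free = int(rng.integers(0, 3)) if k > 0 else 1
        has_link = bool(rng.random() < link_fraction)
        has_zn = bool(rng.random() < zn_fraction) and k > 0

        plan = CysPlan()
        # lay out sequentially with generous sequence spacing
        cursor = 5
        for _ in range(n_pairs):
            gap = int(rng.integers(8, 16))
            if cursor + gap + 32 >= length:
                break
            plan.pairs.append((cursor, cursor + gap))
            cursor += gap + 31
        for _ in range(n_free):
            if cursor + 32 >= length:
                break
            plan.singles.append(cursor)
            cursor += 31
        if has_link and cursor + 32 < length:
            plan.link_singles.append(cursor)
            cursor += 31
        if has_zn and cursor + 35 < length:
            plan.metal_pairs.append((cursor, cursor + 3))

        chain = generate_structure(
            length,
            plan,
            seed=int(rng.integers(0, 2**31 - 1)),
            structure_id=f"C{k:03d}",
            chain_id="A",
        )
        chains.append(chain)

        if "ZN" in chain.bound_metals or "FE" in chain.bound_metals:
            n_excluded += 1
            continue
        n_cys = len(chain.cys_residue_numbers)
        n_link = len(chain.link_cys)
        denom += n_cys - n_link
        numer += 2 * len(plan.pairs)
    truth = {
        "n_cys_disulfide": numer,
        "n_cys_considered": denom,
        "n_excluded_metal": n_excluded,
        "f_prime": numer / denom if denom else float("nan"),
    }
    return chains, truth


def generate_parity_proteome(
    n_proteins: int = 150,
    length_range: tuple[int, int] = (150, 200),
    mode: str = "independent",
    cys_prob: float = 0.035,
    pairs_choices: Sequence[int] = (1, 2, 3),
    seed: int = 0,
    label: str | None = None,
) -> ProteomeSet:
    """Sequence-only proteomes for the even/odd cysteine analysis.

    ``independent`` assigns cysteines per residue with probability
    ``cys_prob`` (default 0.035, chosen so multi-cysteine proteins are well
    populated in the 150-200 aa window); ``paired`` plants only complete
    pairs, so every protein has an even cysteine count.
    """
    if mode not in {"independent", "paired"}:
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    records = []
    for k in range(n_proteins):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = list(_sample_background(rng, length))
        seq[0] = "M"
        if mode == "independent":
            mask = rng.random(length) < cys_prob
            mask[0] = False
            for pos in np.nonzero(mask)[0]:
                seq[pos] = "C"
        else:
            n_pairs = int(rng.choice(pairs_choices))
            positions = rng.choice(
                np.arange(1, length), size=2 * n_pairs, replace=False
            )
            for pos in positions:
                seq[pos] = "C"
        records.append(
            ProteinRecord(id=f"par{k:04d}", sequence="".join(seq), organism="synthetic")
        )
    return ProteomeSet(
        label=label or f"parity_{mode}_seed{seed}", records=records, source="synthetic"
    )
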