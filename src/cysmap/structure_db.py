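"""Structure handling: PDB reading/writing and the structure-based control f'.

The control statistic f' is the fraction of cysteines in deposited
structures that are disulfide-bonded, judged directly from SSBOND records:

    f' = (CYS residues in SSBOND) / (CYS residues observed in ATOM records
                                      minus those in LINK records)

computed over entries that do not bind Zn or Fe (metalloproteins are
excluded wholesale because their cysteines coordinate metals rather than
form disulfides; LINK-record cysteines are excluded from the denominator
for the same reason).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

#: HET elements whose presence excludes an entry from the f' control.
DEFAULT_EXCLUDED_METALS = frozenset({"ZN", "FE"})

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U",
}


class StructureError(ValueError):
    """Raised for malformed or empty structure input."""


@dataclass
class StructureChain:
    """One polypeptide chain plus entry-level annotation.

    ``residues`` lists ``(auth_seq_num, insertion_code, residue_name)`` in
    ATOM-record order; ``ca_coords`` holds a 3-vector in Angstrom per
    residue (None where the CA atom is missing).  SSBOND/LINK/HET metal
    annotation is attached to the owning chain; ``bound_metals`` and
    ``metal_sites`` describe the whole entry.
    """

    structure_id: str
    chain_id: str
    residues: list[tuple[int, str, str]]
    ca_coords: list[np.ndarray | None]
    ssbond_pairs: set[tuple[int, int]] = field(default_factory=set)
    ssbond_cys: set[int] = field(default_factory=set)
    link_cys: set[int] = field(default_factory=set)
    bound_metals: set[str] = field(default_factory=set)
    metal_sites: list[tuple[str, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.ca_coords):
            raise StructureError("residues and ca_coords length mismatch")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        """One-letter sequence of the observed residues (unknowns as X)."""
        return "".join(_THREE_TO_ONE.get(name, "X") for _, _, name in self.residues)

    @property
    def cys_residue_numbers(self) -> list[int]:
        return [num for num, _, name in self.residues if name == "CYS"]

    def residue_index(self, seq_num: int) -> int:
        """Ordinal (0-based position in ``residues``) of an auth residue number."""
        for i, (num, _, _) in enumerate(self.residues):
            if num == seq_num:
                return i
        raise KeyError(seq_num)


@dataclass
class StructureSetSummary:
    n_structures_used: int
    n_excluded_metal: int
    n_cys_considered: int
    n_cys_disulfide: int

    @property
    def f_prime(self) -> float:
        return self.n_cys_disulfide / self.n_cys_considered

    def __post_init__(self) -> None:
        assert self.n_cys_disulfide <= self.n_cys_considered


def _validate_fixed_columns(path: Path) -> None:
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line[:6] in ("ATOM  ", "HETATM"):
            if len(line) < 54:
                raise StructureError(f"{path.name}:{lineno}: truncated coordinate line")
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
                int(line[22:26])
            except ValueError as exc:
                raise StructureError(
                    f"{path.name}:{lineno}: malformed fixed-column field ({exc})"
                ) from None


def read_structure(path: str | Path) -> list[StructureChain]:
    """Parse a PDB file into one :class:`StructureChain` per polypeptide chain.

    Residue lists come from ATOM records (first altloc kept); SSBOND and
    LINK records are attached to the owning chains; HET metal atoms are
    recorded at entry level on every chain.
    """
    path = Path(path)
    _validate_fixed_columns(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path.name}: no models")
    model = st[0]

    info = dict(st.info)
    structure_id = (info.get("_entry.id") or st.name or path.stem).strip() or path.stem

    chains: dict[str, StructureChain] = {}
    metals: set[str] = set()
    metal_sites: list[tuple[str, np.ndarray]] = []
    n_atom_residues = 0
    for ch in model:
        residues: list[tuple[int, str, str]] = []
        coords: list[np.ndarray | None] = []
        for res in ch:
            if res.het_flag == "H":
                for at in res:
                    if at.element.is_metal:
                        sym = at.element.name.upper()
                        metals.add(sym)
                        metal_sites.append(
                            (sym, np.array([at.pos.x, at.pos.y, at.pos.z]))
                        )
                continue
            n_atom_residues += 1
            residues.append((res.seqid.num, res.seqid.icode.strip(), res.name))
            ca = None
            for at in res:
                if at.name == "CA":  # first altloc wins
                    ca = np.array([at.pos.x, at.pos.y, at.pos.z])
                    break
            coords.append(ca)
        if residues:
            chains[ch.name] = StructureChain(
                structure_id=structure_id,
                chain_id=ch.name,
                residues=residues,
                ca_coords=coords,
            )
    if n_atom_residues == 0:
        raise StructureError(f"{path.name}: no ATOM records")

    for con in st.connections:
        p1, p2 = con.partner1, con.partner2
        if con.type == gemmi.ConnectionType.Disulf:
            c1, c2 = chains.get(p1.chain_name), chains.get(p2.chain_name)
            n1, n2 = p1.res_id.seqid.num, p2.res_id.seqid.num
            if c1 is not None:
                c1.ssbond_cys.add(n1)
            if c2 is not None:
                c2.ssbond_cys.add(n2)
            if c1 is c2 and c1 is not None:
                c1.ssbond_pairs.add(tuple(sorted((n1, n2))))
        else:  # LINK and other covalent/coordination records
            for p in (p1, p2):
                ch = chains.get(p.chain_name)
                if ch is not None and p.res_id.name == "CYS":
                    ch.link_cys.add(p.res_id.seqid.num)

    for ch in chains.values():
        ch.bound_metals = set(metals)
        ch.metal_sites = list(metal_sites)
    return list(chains.values())


def read_structure_dir(directory: str | Path) -> dict[str, dict[str, StructureChain]]:
    """Read every ``*.pdb`` in a directory, keyed by structure id then chain id."""
    out: dict[str, dict[str, StructureChain]] = {}
    for p in sorted(Path(directory).glob("*.pdb")):
        for ch in read_structure(p):
            out.setdefault(ch.structure_id, {})[ch.chain_id] = ch
    if not out:
        raise StructureError(f"no .pdb files in {directory}")
    return out


def sequence_identity(a: str, b: str) -> float:
    """Identity of two sequences as 1 - edit_distance / max_length."""
    # simple banded-free Levenshtein; chains are short enough
    if a == b:
        return 1.0
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        ai = a[i - 1]
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (ai != b[j - 1]),
            )
        prev = cur
    return 1.0 - prev[m] / max(n, m)


def dedupe_chains(
    chains: Sequence[StructureChain], identity_threshold: float = 0.95
) -> list[StructureChain]:
    """Greedy redundancy removal keeping the first-seen representative.

    A chain is dropped when its sequence is at least ``identity_threshold``
    identical to a previously kept chain.  Used to approximate "unique
    reported structures" when pooling a structure set for f'.
    """
    kept: list[StructureChain] = []
    for ch in chains:
        if all(
            sequence_identity(ch.sequence, k.sequence) < identity_threshold
            for k in kept
        ):
            kept.append(ch)
    return kept


def structure_disulfide_fraction(
    structures: Iterable[StructureChain],
    excluded_metals: frozenset[str] | set[str] = DEFAULT_EXCLUDED_METALS,
) -> StructureSetSummary:
    """Compute the control fraction f' over a set of structure chains.

    Entries (grouped by structure id) whose bound metals intersect
    ``excluded_metals`` are excluded entirely.  The denominator counts CYS
    residues observed in ATOM records of retained chains minus those in
    LINK records; the numerator counts retained CYS residues in SSBOND
    records.  Raises :class:`StructureError` when no eligible cysteine
    remains.
    """
    excluded_metals = {m.upper() for m in excluded_metals}
    by_entry: dict[str, list[StructureChain]] = defaultdict(list)
    for ch in structures:
        by_entry[ch.structure_id].append(ch)
    if not by_entry:
        raise StructureError("empty structure set")

    n_used = n_excluded = 0
    denom = numer = 0
    for entry_id in sorted(by_entry):
        entry = by_entry[entry_id]
        if any(ch.bound_metals & excluded_metals for ch in entry):
            n_excluded += 1
            continue
        n_used += 1
        for ch in entry:
            for num in ch.cys_residue_numbers:
                if num in ch.link_cys:
                    continue
                denom += 1
                if num in ch.ssbond_cys:
                    numer += 1
    if denom == 0:
        raise StructureError("no eligible cysteines")
    return StructureSetSummary(
        n_structures_used=n_used,
        n_excluded_metal=n_excluded,
        n_cys_considered=denom,
        n_cys_disulfide=numer,
    )


# ---------------------------------------------------------------------------
# PDB writer (fixed columns; used by the synthetic-data generator)
# ---------------------------------------------------------------------------

def _pad_atom_name(name: str, element: str) -> str:
    # two-letter elements start in column 13, one-letter in column 14
    if len(element) == 2:
        return f"{name:<4s}"
    return f" {name:<3s}"


def _atom_line(
    record: str,
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    xyz: np.ndarray,
    element: str,
) -> str:
    return (
        f"{record:<6s}{serial:5d} {_pad_atom_name(name, element)} {resname:>3s} "
        f"{chain:1s}{resseq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def _link_line(
    chain: str, cys_num: int, sym: str, metal_num: int, dist: float
) -> str:
    return (
        "LINK        "
        f"{' SG ':4s} CYS {chain:1s}{cys_num:4d} "
        + " " * 15
        + f"{sym:<4s} {sym:>3s} {chain:1s}{metal_num:4d} "
        + f"  {'1555':>6s} {'1555':>6s} {dist:5.2f}"
    )


def write_structure(chains: Sequence[StructureChain], path: str | Path) -> None:
    """Write chains (CA-only plus HET metals) as a fixed-column PDB file.

    SSBOND and LINK records are emitted from the chain annotation so that a
    written file round-trips through :func:`read_structure`.
    """
    path = Path(path)
    lines: list[str] = []
    sid = (chains[0].structure_id[:4] if chains else "XXXX").upper()
    lines.append(
        f"HEADER    SYNTHETIC STRUCTURE                     01-JAN-20   {sid:<4s}"
    )

    metal_sites = chains[0].metal_sites if chains else []
    metal_resnum = {i: 9000 + i for i in range(len(metal_sites))}

    ser = 0
    for ch in chains:
        for a, b in sorted(ch.ssbond_pairs):
            ser += 1
            lines.append(
                f"SSBOND {ser:3d} CYS {ch.chain_id} {a:4d}    CYS {ch.chain_id} {b:4d}"
            )
    for ch in chains:
        for num in sorted(ch.link_cys):
            ca = ch.ca_coords[ch.residue_index(num)]
            if metal_sites and ca is not None:
                i = min(
                    range(len(metal_sites)),
                    key=lambda k: float(np.linalg.norm(metal_sites[k][1] - ca)),
                )
                sym, pos = metal_sites[i]
                d = min(float(np.linalg.norm(pos - ca)), 9.99)
                lines.append(_link_line(ch.chain_id, num, sym, metal_resnum[i], d))

    serial = 0
    for ch in chains:
        for (num, _icode, name), ca in zip(ch.residues, ch.ca_coords):
            if ca is None:
                continue
            serial += 1
            lines.append(
                _atom_line("ATOM", serial, "CA", name, ch.chain_id, num, ca, "C")
            )
        lines.append("TER")
    hetatm_chain = chains[0].chain_id if chains else "A"
    for i, (sym, pos) in enumerate(metal_sites):
        serial += 1
        lines.append(
            _atom_line("HETATM", serial, sym, sym, hetatm_chain, metal_resnum[i], pos, sym)
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
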