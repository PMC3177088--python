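"""Eligibility filters applied before sequence-structure mapping.

Three rules are implemented:

* a minimum raw cysteine count per protein (default 2) — proteins below it
  cannot contain an intramolecular disulfide;
* a spacing mask that drops cysteines falling within a few residues of each
  other (default 5), a sequence-level proxy for metal-binding motifs such as
  CXXC whose cysteines would otherwise be mistaken for disulfide partners;
* removal of secreted/periplasmic proteins, whose disulfides form in
  oxidizing extracytosolic compartments regardless of organism.

The spacing mask affects cysteine *eligibility* only, never protein
retention; the minimum-count filter uses raw counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .proteome_io import ProteinRecord, ProteomeSet

#: Residues counted as hydrophobic when scanning for a signal-peptide h-region.
HYDROPHOBIC = frozenset("AILMFVWC")
#: Small/neutral residues accepted at the −3/−1 positions of a cleavage site.
CLEAVAGE_SET = frozenset("AGSCTV")


@dataclass
class FilterParams:
    min_cys: int = 2
    cluster_spacing: int = 5
    signal_filter_mode: str = "heuristic"  # heuristic | exclusion_list | off

    def __post_init__(self) -> None:
        if self.min_cys < 0 or self.cluster_spacing < 0:
            raise ValueError("min_cys and cluster_spacing must be >= 0")
        if self.signal_filter_mode not in {"heuristic", "exclusion_list", "off"}:
            raise ValueError(f"unknown signal_filter_mode {self.signal_filter_mode!r}")


@dataclass
class FilterReport:
    """Accounting of filter dispositions; n_input = removed + retained."""

    n_input: int
    n_removed_low_cys: int
    n_removed_secreted: int
    n_retained: int
    eligible: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert (
            self.n_input
            == self.n_removed_low_cys + self.n_removed_secreted + self.n_retained
        )


def filter_min_cysteines(
    proteome: ProteomeSet, min_cys: int = 2
) -> tuple[ProteomeSet, int]:
    """Retain proteins whose *raw* cysteine count is >= ``min_cys``."""
    retained = [r for r in proteome if r.n_cys >= min_cys]
    out = ProteomeSet(label=proteome.label, records=retained, source=proteome.source)
    return out, len(proteome) - len(retained)


def mask_clustered_cysteines(
    cys_positions: Sequence[int], spacing: int = 5
) -> list[int]:
    """Drop every cysteine with another cysteine at sequence separation <= spacing.

    Both members of a close pair are removed.  Idempotent; the result is
    strictly increasing.
    """
    pos = list(cys_positions)
    drop = set()
    for a in range(len(pos)):
        for b in range(a + 1, len(pos)):
            if pos[b] - pos[a] <= spacing:
                drop.add(pos[a])
                drop.add(pos[b])
    return [p for p in pos if p not in drop]


def predict_signal_peptide(
    record_or_sequence: ProteinRecord | str,
) -> tuple[float, bool]:
    """Heuristic N-terminal signal-peptide detector.

    A sequence is called secreted when all three hold:

    a. a positively charged K or R within the first 7 residues (n-region);
    b. a 10-residue window starting within residues 2-25 (1-based) with at
       least 8 residues from :data:`HYDROPHOBIC` (h-region);
    c. a candidate cleavage position p within residues 15-40 whose −3 and −1
       residues (1-based p−3 and p−1) are both in :data:`CLEAVAGE_SET`.

    Returns ``(score, is_secreted)`` where score is the fraction of
    conditions met.  This is a self-contained stand-in for trained
    signal-peptide predictors; for exact reproduction of an external tool's
    calls use the exclusion-list mode of :func:`filter_extracytoplasmic`.
    """
    seq = (
        record_or_sequence.sequence
        if isinstance(record_or_sequence, ProteinRecord)
        else record_or_sequence
    )
    n = len(seq)

    cond_a = any(aa in "KR" for aa in seq[:7])

    cond_b = False
    for start in range(1, 25):  # 1-based residues 2..25
        window = seq[start : start + 10]
        if len(window) < 10:
            break
        if sum(aa in HYDROPHOBIC for aa in window) >= 8:
            cond_b = True
            break

    cond_c = False
    for p in range(15, min(40, n) + 1):  # 1-based cleavage position
        if seq[p - 4] in CLEAVAGE_SET and seq[p - 2] in CLEAVAGE_SET:
            cond_c = True
            break

    met = cond_a + cond_b + cond_c
    return met / 3.0, met == 3


def read_exclusion_list(path: str | Path) -> set[str]:
    """Plain-text exclusion list: one accession per line, '#' comments."""
    ids: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.add(line)
    return ids


def filter_extracytoplasmic(
    proteome: ProteomeSet,
    mode: str = "heuristic",
    exclusion_list: Iterable[str] | None = None,
) -> tuple[ProteomeSet, int]:
    """Remove secreted/periplasmic proteins.

    ``mode='heuristic'`` applies :func:`predict_signal_peptide`;
    ``mode='exclusion_list'`` removes the listed ids (ids absent from the
    proteome produce a warning, not an error); ``mode='off'`` is the
    identity.
    """
    if mode == "off":
        return proteome, 0
    if mode == "exclusion_list":
        if exclusion_list is None:
            raise ValueError("exclusion_list mode requires an id list")
        excl = set(exclusion_list)
        missing = excl - set(proteome.ids)
        if missing:
            warnings.warn(
                f"{len(missing)} exclusion-list ids not in proteome "
                f"(e.g. {sorted(missing)[0]!r})",
                stacklevel=2,
            )
        retained = [r for r in proteome if r.id not in excl]
    elif mode == "heuristic":
        retained = [r for r in proteome if not predict_signal_peptide(r)[1]]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = ProteomeSet(label=proteome.label, records=retained, source=proteome.source)
    return out, len(proteome) - len(retained)


def apply_filters(
    proteome: ProteomeSet,
    params: FilterParams | None = None,
    exclusion_list: Iterable[str] | None = None,
) -> tuple[ProteomeSet, FilterReport]:
    """Run the documented filter order: min-cys -> secretion -> spacing mask.

    Returns the retained proteome plus a :class:`FilterReport` whose
    ``eligible`` map gives, per retained protein, the cysteine positions
    still eligible for structure mapping after the spacing mask.
    """
    params = params or FilterParams()
    kept, n_low = filter_min_cysteines(proteome, params.min_cys)
    kept, n_secr = filter_extracytoplasmic(
        kept, params.signal_filter_mode, exclusion_list
    )
    eligible = {
        r.id: tuple(mask_clustered_cysteines(r.cys_positions, params.cluster_spacing))
        for r in kept
    }
    report = FilterReport(
        n_input=len(proteome),
        n_removed_low_cys=n_low,
        n_removed_secreted=n_secr,
        n_retained=len(kept),
        eligible=eligible,
    )
    return kept, report
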