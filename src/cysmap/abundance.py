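"""Proteome-level disulfide abundance: the parameter f, tiers, strain
deduplication and the f vs f' comparison.

f is a pooled ratio — total hit cysteines over total mapped cysteines (m)
across the proteome — not a mean of per-protein fractions.  Organisms are
tiered at f > 0.15 (significant), > 0.25 (high) and > 0.35 (very high),
with f <= 0.15 as background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import pearsonr

from .homology_map import MappingResult

TIER_THRESHOLDS = (0.15, 0.25, 0.35)
TIERS = ("background", "significant", "high", "very_high")


@dataclass
class ProteomeSummary:
    label: str
    n_proteins_mapped: int
    m: int  # total mapped cysteines
    n_hits: int

    def __post_init__(self) -> None:
        assert self.n_hits <= self.m

    @property
    def f(self) -> float:
        return self.n_hits / self.m

    @property
    def tier(self) -> str:
        return classify_abundance(self.f)


@dataclass
class DedupParams:
    tolerance: float = 0.10

    def __post_init__(self) -> None:
        if not 0 <= self.tolerance < 1:
            raise ValueError("tolerance must be in [0, 1)")


def protein_f(mapping: MappingResult) -> tuple[int, int, float | None]:
    """Per-protein (hits, mapped, fraction); fraction is None when nothing
    mapped.  A protein with a single mapped cysteine necessarily has zero
    hits (a hit needs another *mapped* partner)."""
    hits, mapped = mapping.n_hits, mapping.n_mapped
    return hits, mapped, (hits / mapped if mapped else None)


def proteome_f(
    per_protein: Iterable[tuple[int, int]], label: str = ""
) -> ProteomeSummary:
    """Pool per-protein (hits, mapped) tallies into the proteome-level f.

    The ratio is pooled (sum of hits over sum of mapped), which makes it
    invariant to how proteins are batched.  Raises ValueError when no
    cysteine mapped at all.
    """
    total_hits = total_mapped = n_proteins = 0
    for hits, mapped in per_protein:
        if mapped:
            n_proteins += 1
        total_hits += hits
        total_mapped += mapped
    if total_mapped == 0:
        raise ValueError("no mapped cysteines")
    return ProteomeSummary(
        label=label, n_proteins_mapped=n_proteins, m=total_mapped, n_hits=total_hits
    )


def classify_abundance(f: float) -> str:
    """Tier an f value; thresholds are strict (f = 0.15 is still background)."""
    if not 0 <= f <= 1:
        raise ValueError("f must be in [0, 1]")
    tier = TIERS[0]
    for threshold, name in zip(TIER_THRESHOLDS, TIERS[1:]):
        if f > threshold:
            tier = name
    return tier


def dedup_strains(
    summaries: Sequence[ProteomeSummary],
    species_key: Mapping[str, str],
    params: DedupParams | None = None,
) -> list[ProteomeSummary]:
    """Drop re-sequenced strains that duplicate their parent's results.

    Within each species the first-listed summary is the parent; a later
    strain is removed when its mapped-protein count is within
    ``tolerance`` (default +/-10%) of the parent's.
    """
    params = params or DedupParams()
    parent: dict[str, ProteomeSummary] = {}
    kept: list[ProteomeSummary] = []
    for s in summaries:
        species = species_key[s.label]
        p = parent.get(species)
        if p is None:
            parent[species] = s
            kept.append(s)
        elif abs(s.n_proteins_mapped - p.n_proteins_mapped) > params.tolerance * p.n_proteins_mapped:
            kept.append(s)
    return kept


def compare_f_fprime(pairs: Sequence[tuple[float, float]]) -> float:
    """Pearson correlation between mapping-based f and structure-based f'."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 (f, f') pairs")
    f_vals = [a for a, _ in pairs]
    fp_vals = [b for _, b in pairs]
    return float(pearsonr(f_vals, fp_vals).statistic)
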