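"""Even-versus-odd cysteine counting.

In an organism whose cytosolic cysteines are mostly disulfide-paired,
proteins with an even number of cysteines are over-represented (a "sawtooth"
in the count-vs-cysteine-number histogram).  This module tabulates protein
counts by cysteine number inside a length window and summarises the
even-bias with a scalar statistic and an exact binomial test.  The scalar
statistic is an extension of the visual analysis and is labelled as such in
report output.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from scipy.stats import binomtest

from .proteome_io import ProteomeSet


@dataclass
class ParityParams:
    length_min: int = 150
    length_max: int = 200  # inclusive
    max_cys_bin: int = 10  # histogram tail pooled as ">=max" in report output

    def __post_init__(self) -> None:
        if self.length_min > self.length_max:
            raise ValueError("length_min must be <= length_max")


@dataclass
class ParityTable:
    """Protein counts keyed by raw cysteine number within the length window.

    ``even_ge2`` counts proteins with an even cysteine number >= 2 and
    ``odd_ge3`` those with an odd number >= 3; proteins with 0 or 1
    cysteines appear in ``counts`` but enter neither statistic.
    """

    counts: dict[int, int]
    n_total: int = field(init=False)
    even_ge2: int = field(init=False)
    odd_ge3: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_total = sum(self.counts.values())
        self.even_ge2 = sum(
            c for n, c in self.counts.items() if n >= 2 and n % 2 == 0
        )
        self.odd_ge3 = sum(c for n, c in self.counts.items() if n >= 3 and n % 2 == 1)


def parity_table(proteome: ProteomeSet, params: ParityParams | None = None) -> ParityTable:
    """Tabulate cysteine-number counts for proteins inside the length window.

    The proteome is expected to be secretion-filtered already; the spacing
    mask does not apply here (whole-protein cysteine totals are counted).
    An empty window yields a table with ``n_total == 0``.
    """
    params = params or ParityParams()
    counts: Counter[int] = Counter()
    for rec in proteome:
        if params.length_min <= rec.length <= params.length_max:
            counts[rec.n_cys] += 1
    return ParityTable(counts=dict(counts))


def parity_bias(table: ParityTable) -> tuple[float, float]:
    """Even-bias scalar and its exact binomial p-value.

    ``bias = (even_ge2 - odd_ge3) / (even_ge2 + odd_ge3)`` in [-1, 1];
    the p-value is a two-sided exact binomial test of ``even_ge2`` successes
    in ``even_ge2 + odd_ge3`` trials at null probability 0.5.
    """
    n = table.even_ge2 + table.odd_ge3
    if n == 0:
        raise ValueError("no multi-cysteine proteins")
    bias = (table.even_ge2 - table.odd_ge3) / n
    p_value = binomtest(table.even_ge2, n, 0.5).pvalue
    return bias, float(p_value)
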