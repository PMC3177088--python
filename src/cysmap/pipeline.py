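"""Orchestration of the survey stages plus TSV report writers.

``run_survey`` is the whole mapping pipeline for one proteome: filters ->
homolog search -> global realignment -> cysteine placement -> pooled f.
Every protein ends up in exactly one disposition (filtered / unmapped /
mapped).  ``run_parity`` and ``run_fprime`` wrap the counting analyses.
Output TSVs carry '#'-prefixed metadata lines (config hash, seed) so a
rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import abundance
from .abundance import ProteomeSummary
from .filters import FilterParams, FilterReport, apply_filters
from .homology_map import (
    MappingResult,
    SearchParams,
    global_realign,
    map_cysteines,
    proximity_hits,
    search_homologs,
)
from .parity import ParityParams, ParityTable, parity_bias, parity_table
from .proteome_io import ProteomeSet
from .structure_db import (
    StructureChain,
    StructureSetSummary,
    dedupe_chains,
    structure_disulfide_fraction,
)


@dataclass
class SurveyParams:
    filter_params: FilterParams = field(default_factory=FilterParams)
    search_params: SearchParams = field(default_factory=SearchParams)
    cutoff_angstrom: float = 8.0
    semiglobal: bool = True


@dataclass
class ProteinRow:
    """Per-protein disposition in the survey."""

    protein_id: str
    disposition: str  # filtered | unmapped | mapped
    reason: str = ""  # low_cys | secreted | few_eligible | no_hit | no_mapped_cys
    structure_id: str = ""
    chain_id: str = ""
    evalue: float | None = None
    identity: float | None = None
    n_eligible: int = 0
    n_mapped: int = 0
    n_hits: int = 0


@dataclass
class SurveyResult:
    summary: ProteomeSummary
    rows: list[ProteinRow]
    report: FilterReport
    mappings: dict[str, MappingResult] = field(default_factory=dict)


def _lookup_chain(
    structures: Mapping[str, Mapping[str, StructureChain]], target_id: str
) -> StructureChain:
    entry, _, chain_id = target_id.rpartition("_")
    try:
        return structures[entry][chain_id]
    except KeyError:
        raise KeyError(f"structure {target_id!r} not found in structure set") from None


def run_survey(
    proteome: ProteomeSet,
    structures: Mapping[str, Mapping[str, StructureChain]],
    library: Mapping[str, str],
    params: SurveyParams | None = None,
    tabular_path: str | Path | None = None,
    exclusion_list: Iterable[str] | None = None,
) -> SurveyResult:
    """Estimate the disulfide abundance parameter f for one proteome.

    ``structures`` maps structure id -> chain id -> chain; ``library`` maps
    'entry_chain' ids to structure sequences (the search space).  With
    ``tabular_path`` the search step reads precomputed blast-tabular hits
    instead of aligning internally.
    """
    params = params or SurveyParams()
    kept, report = apply_filters(proteome, params.filter_params, exclusion_list)
    kept_ids = set(kept.ids)

    rows: list[ProteinRow] = []
    mappings: dict[str, MappingResult] = {}
    tallies: list[tuple[int, int]] = []
    for rec in proteome:
        if rec.id not in kept_ids:
            reason = "low_cys" if rec.n_cys < params.filter_params.min_cys else "secreted"
            rows.append(ProteinRow(rec.id, "filtered", reason))
            continue
        eligible = report.eligible[rec.id]
        if len(eligible) < 2:
            rows.append(
                ProteinRow(rec.id, "unmapped", "few_eligible", n_eligible=len(eligible))
            )
            continue
        hits = search_homologs(
            rec, library, params.search_params, tabular_path=tabular_path
        )
        if not hits:
            rows.append(
                ProteinRow(rec.id, "unmapped", "no_hit", n_eligible=len(eligible))
            )
            continue
        best = hits[0]
        chain = _lookup_chain(structures, best.target_id)
        aln = global_realign(
            rec.sequence,
            chain.sequence,
            semiglobal=params.semiglobal,
            query_id=rec.id,
            target_id=best.target_id,
        )
        mapping = map_cysteines(aln, chain, eligible, cutoff=params.cutoff_angstrom)
        if mapping.n_mapped == 0:
            rows.append(
                ProteinRow(
                    rec.id,
                    "unmapped",
                    "no_mapped_cys",
                    structure_id=chain.structure_id,
                    chain_id=chain.chain_id,
                    evalue=best.evalue,
                    identity=aln.identity,
                    n_eligible=len(eligible),
                )
            )
            continue
        n_hits, _pairs = proximity_hits(mapping, params.cutoff_angstrom)
        tallies.append((n_hits, mapping.n_mapped))
        mappings[rec.id] = mapping
        rows.append(
            ProteinRow(
                rec.id,
                "mapped",
                structure_id=chain.structure_id,
                chain_id=chain.chain_id,
                evalue=best.evalue,
                identity=aln.identity,
                n_eligible=len(eligible),
                n_mapped=mapping.n_mapped,
                n_hits=n_hits,
            )
        )

    summary = abundance.proteome_f(tallies, label=proteome.label)
    return SurveyResult(summary=summary, rows=rows, report=report, mappings=mappings)


def run_parity(
    proteome: ProteomeSet,
    filter_params: FilterParams | None = None,
    parity_params: ParityParams | None = None,
    exclusion_list: Iterable[str] | None = None,
) -> tuple[ParityTable, float, float]:
    """Secretion-filter the proteome, then tabulate even/odd cysteine counts.

    The minimum-cysteine filter and the spacing mask do not apply here:
    the analysis counts whole-protein cysteine totals, including 0 and 1.
    Returns (table, bias, p_value).
    """
    from .filters import filter_extracytoplasmic

    filter_params = filter_params or FilterParams()
    kept, _ = filter_extracytoplasmic(
        proteome, filter_params.signal_filter_mode, exclusion_list
    )
    table = parity_table(kept, parity_params)
    bias, p = parity_bias(table)
    return table, bias, p


def run_fprime(
    chains: Sequence[StructureChain],
    excluded_metals: Iterable[str] = ("ZN", "FE"),
    dedupe: bool = False,
    identity_threshold: float = 0.95,
) -> StructureSetSummary:
    """Compute the structure-database control f' for a set of chains."""
    chains = list(chains)
    if dedupe:
        chains = dedupe_chains(chains, identity_threshold)
    return structure_disulfide_fraction(chains, set(excluded_metals))


# ---------------------------------------------------------------------------
# report writers (1-based residue numbering at this boundary)
# ---------------------------------------------------------------------------

def _meta_lines(seed: int | None, config: Mapping | None) -> list[str]:
    blob = json.dumps(config or {}, sort_keys=True, default=str)
    digest = hashlib.sha256(blob.encode()).hexdigest()[:12]
    lines = [f"# config_hash: {digest}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    return lines


def write_survey_tsv(
    result: SurveyResult,
    path: str | Path,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    s = result.summary
    lines = _meta_lines(seed, config)
    lines.append("organism\tn_proteins_mapped\tm\tn_hits\tf\ttier")
    lines.append(
        f"{s.label}\t{s.n_proteins_mapped}\t{s.m}\t{s.n_hits}\t{s.f:.6f}\t{s.tier}"
    )
    Path(path).write_text("\n".join(lines) + "\n")


def write_mapping_tsv(
    result: SurveyResult,
    path: str | Path,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    lines = _meta_lines(seed, config)
    lines.append(
        "protein_id\tdisposition\treason\tstructure_id\tchain_id\tevalue\t"
        "identity\tn_eligible\tn_mapped\tn_hits"
    )
    for r in result.rows:
        ev = f"{r.evalue:.3g}" if r.evalue is not None else ""
        ident = f"{r.identity:.3f}" if r.identity is not None else ""
        lines.append(
            f"{r.protein_id}\t{r.disposition}\t{r.reason}\t{r.structure_id}\t"
            f"{r.chain_id}\t{ev}\t{ident}\t{r.n_eligible}\t{r.n_mapped}\t{r.n_hits}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_parity_tsv(
    table: ParityTable,
    bias: float,
    p_value: float,
    path: str | Path,
    organism: str = "",
    max_cys_bin: int = 10,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    pooled: dict[int, int] = {}
    for n_cys, count in sorted(table.counts.items()):
        pooled[min(n_cys, max_cys_bin)] = pooled.get(min(n_cys, max_cys_bin), 0) + count
    lines = _meta_lines(seed, config)
    lines.append("organism\tn_cys\tcount")
    for n_cys in sorted(pooled):
        label = str(n_cys) if n_cys < max_cys_bin else f">={max_cys_bin}"
        lines.append(f"{organism}\t{label}\t{pooled[n_cys]}")
    lines.append(
        f"# summary (extension): even_ge2={table.even_ge2} odd_ge3={table.odd_ge3} "
        f"bias={bias:.4f} p_value={p_value:.3g}"
    )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fprime_tsv(
    summary: StructureSetSummary,
    path: str | Path,
    organism: str = "",
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    lines = _meta_lines(seed, config)
    lines.append(
        "organism\tn_structures_used\tn_excluded_metal\tn_cys_considered\t"
        "n_cys_disulfide\tf_prime"
    )
    lines.append(
        f"{organism}\t{summary.n_structures_used}\t{summary.n_excluded_metal}\t"
        f"{summary.n_cys_considered}\t{summary.n_cys_disulfide}\t{summary.f_prime:.6f}"
    )
    Path(path).write_text("\n".join(lines) + "\n")


def write_compare_tsv(
    rows: Sequence[tuple[str, float, float]],
    r_value: float,
    path: str | Path,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    lines = _meta_lines(seed, config)
    lines.append("organism\tf\tf_prime")
    for org, f, fp in rows:
        lines.append(f"{org}\t{f:.6f}\t{fp:.6f}")
    lines.append(f"# pearson_r: {r_value:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
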