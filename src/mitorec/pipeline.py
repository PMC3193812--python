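"""End-to-end orchestration of the two analyses:

* recombination analysis (WT vs msh1 first/advanced generation):
  repeat discovery -> mapping -> discordant-pair clustering -> support
  filter -> active repeats -> polarity / fate -> gene conversion;
* ecotype panel analysis: per-ecotype SNP calling -> SV typing ->
  stoichiometry -> TN93/NJ phylogeny -> groups -> SV/group concordance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import conversion as conv
from . import ecotype_phylo as eco
from . import junction_detect as jd
from . import polarity_class as pc
from . import synthetic_data as sd
from .align_core import RepeatPair, find_repeat_pairs, realign_pair
from .formats_io import GenomeSeq
from .mapper import GenomeIndex, PlacementSet, base_pileup, coverage_track, map_reads

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# msh1 recombination pipeline
# ---------------------------------------------------------------------------

@dataclass
class Msh1Fixture:
    truth: sd.ReferenceTruth
    recombinants: list[sd.RecombinantMolecule]
    libraries: dict[str, sd.ReadLibrary]
    seed: int


def simulate_msh1(
    genome_length: int = 100_000,
    seed: int = 1,
    profile: str = "standard",
    catalog: Optional[list[sd.RepeatSpec]] = None,
) -> Msh1Fixture:
    """Default msh1 fixture: packaged 47-pair catalog, recombinants planted
    at every pair, WT + two mutant-generation libraries."""
    catalog = catalog if catalog is not None else sd.default_catalog(seed)
    truth = sd.build_reference(genome_length, catalog, seed)
    recombinants = [
        sd.make_recombinant(truth, r.name, seed=seed) for r in truth.repeats
    ]
    specs = sd.default_library_specs(truth, seed, profile=profile)
    libraries = {
        name: sd.simulate_library(truth, recombinants, spec, seed, stream=i)
        for i, (name, spec) in enumerate(sorted(specs.items()))
    }
    return Msh1Fixture(truth=truth, recombinants=recombinants, libraries=libraries, seed=seed)


@dataclass
class Msh1Results:
    genome: GenomeSeq
    catalog: list[RepeatPair]
    placements: dict[str, PlacementSet]
    median_depth: dict[str, float]
    clusters: list[jd.JunctionCluster]
    selected: list[jd.JunctionCluster]
    calls: jd.ActiveRepeatCalls
    flank_tables: dict[str, pc.FlankChangeTable]
    polarity: dict[str, pc.PolarityCall]
    junction_support: dict[str, dict[str, float]]
    conversion_reports: dict[str, conv.ConversionReport]
    direction: dict[str, conv.DirectionSummary]
    trend: pd.DataFrame
    trend_correlation: float
    stage_counts: dict[str, int] = field(default_factory=dict)

    def active_table(self) -> pd.DataFrame:
        rows = []
        for pair, clusters in self.calls.active:
            rows.append(
                {
                    "repeat": pair.name,
                    "copy1_start": pair.copy1.start + 1,
                    "copy1_end": pair.copy1.end,
                    "copy2_start": pair.copy2.start + 1,
                    "copy2_end": pair.copy2.end,
                    "length": pair.length,
                    "identity": round(pair.identity, 2),
                    "orientation": pair.orientation,
                    "n_clusters": len(clusters),
                    "support": max(c.support for c in clusters),
                    "donor": self.polarity.get(pair.name).donor
                    if pair.name in self.polarity
                    else None,
                    "fate_class": self.polarity.get(pair.name).fate_class
                    if pair.name in self.polarity
                    else "",
                }
            )
        return pd.DataFrame(rows)


def analyze_recombination(
    genome: GenomeSeq,
    libraries: dict[str, object],
    wt_library: str = "WT",
    require_libraries: Sequence[str] = ("msh1_gen1", "msh1_adv"),
    min_support: int = jd.DEFAULT_MIN_SUPPORT,
    min_repeat_length: int = 50,
    min_identity: float = 85.0,
    insert_mean: int = sd.INSERT_MEAN,
    insert_sd: int = sd.INSERT_SD,
    read_length: int = sd.READ_LENGTH,
    subtract_wt: bool = True,
    adv_library: str = "msh1_adv",
) -> Msh1Results:
    """Run the recombination analysis.

    ``libraries`` maps condition -> ReadLibrary (mapped internally) or an
    already classified PlacementSet (e.g. from SAM ingest).
    """
    if subtract_wt and wt_library not in libraries:
        raise ValueError(
            f"wild-type library {wt_library!r} required for background subtraction"
        )
    counts: dict[str, int] = {}
    catalog = find_repeat_pairs(
        genome, min_length=min_repeat_length, min_identity=min_identity,
        flank_window=insert_mean,
    )
    counts["catalog_pairs"] = len(catalog)
    log.info("discovered %d repeat pairs", len(catalog))

    index = GenomeIndex(genome, k=read_length // 2)
    placements: dict[str, PlacementSet] = {}
    for name, lib in libraries.items():
        if isinstance(lib, PlacementSet):
            placements[name] = lib
        else:
            placements[name] = map_reads(lib, index)
        log.info("library %s: %s", name, placements[name].counts())
    median_depth = {
        name: float(np.median(coverage_track(pl))) for name, pl in placements.items()
    }

    clusters = jd.cluster_discordant(placements)
    counts["clusters"] = len(clusters)
    selected = jd.filter_clusters(
        clusters,
        min_support=min_support,
        require_libraries=require_libraries,
        wt_library=wt_library if subtract_wt else None,
        known_libraries=set(placements),
    )
    counts["selected_clusters"] = len(selected)
    calls = jd.call_active_repeats(
        selected, catalog, genome, pad=insert_mean + 2 * insert_sd
    )
    counts["active_repeats"] = len(calls.active)
    counts["nhej_candidates"] = len(calls.nhej_candidates)

    mutant_libs = [l for l in placements if l != wt_library]
    flank_tables: dict[str, pc.FlankChangeTable] = {}
    polarity: dict[str, pc.PolarityCall] = {}
    junction_support: dict[str, dict[str, float]] = {}
    conversion_reports: dict[str, conv.ConversionReport] = {}
    direction: dict[str, conv.DirectionSummary] = {}
    gen_pair = [l for l in require_libraries if l in placements]
    for pair, pclusters in calls.active:
        best = max(pclusters, key=lambda c: c.support)
        table = pc.flank_change_table(
            pair, placements, median_depth, wt_library=wt_library,
            window=insert_mean, catalog=catalog,
        )
        flank_tables[pair.name] = table
        support_norm = {
            lib: sum(c.net_support(lib, wt_library) for c in pclusters)
            / median_depth[lib]
            for lib in mutant_libs
        }
        junction_support[pair.name] = support_norm
        call = pc.call_polarity(table, best, pair, library=adv_library
                                if adv_library in table.changes else None)
        if len(gen_pair) >= 2:
            call.fate_class = pc.classify_fate(
                table, support_norm, gen1=gen_pair[0], adv=gen_pair[-1]
            )
        polarity[pair.name] = call
        polys = conv.catalog_polymorphisms(pair, genome)
        if polys and adv_library in placements:
            report = conv.recombinant_consensus(
                placements[adv_library], pair, polys, best,
                donor=call.donor if call.donor else 1,
                library=adv_library,
            )
            conversion_reports[pair.name] = report
            direction[pair.name] = conv.resolve_direction(report, call.donor)
    trend, corr = pc.generation_trend(
        flank_tables,
        junction_support,
        generations=tuple(gen_pair) if len(gen_pair) >= 2 else ("msh1_gen1", "msh1_adv"),
    )
    log.info("stage counts: %s", counts)
    return Msh1Results(
        genome=genome, catalog=catalog, placements=placements,
        median_depth=median_depth, clusters=clusters, selected=selected,
        calls=calls, flank_tables=flank_tables, polarity=polarity,
        junction_support=junction_support, conversion_reports=conversion_reports,
        direction=direction, trend=trend, trend_correlation=corr,
        stage_counts=counts,
    )


def match_to_truth(
    results: Msh1Results, truth: sd.ReferenceTruth, min_overlap: float = 0.95
) -> dict[str, str]:
    """Map discovered active repeats to planted truth repeats by reciprocal
    interval overlap (>= min_overlap on both copies)."""
    out = {}
    for pair, _ in results.calls.active:
        for planted in truth.repeats:
            o1 = pair.copy1.overlap_len(planted.copy1) / max(
                pair.copy1.length, planted.copy1.length
            )
            o2 = pair.copy2.overlap_len(planted.copy2) / max(
                pair.copy2.length, planted.copy2.length
            )
            if o1 >= min_overlap and o2 >= min_overlap:
                out[pair.name] = planted.name
                break
    return out


# ---------------------------------------------------------------------------
# ecotype panel pipeline
# ---------------------------------------------------------------------------

@dataclass
class PanelFixture:
    truth: sd.PanelTruth
    libraries: dict[str, sd.ReadLibrary]
    seed: int


def simulate_panel(
    seed: int = 1,
    genome_length: int = 50_000,
    spec: Optional[sd.EcotypePanelSpec] = None,
) -> PanelFixture:
    spec = spec or sd.EcotypePanelSpec()
    reference = sd.build_reference(
        genome_length, sd.panel_reference_catalog(seed), seed, n_decoys=4
    )
    truth = sd.make_ecotype_panel(reference, spec, seed)
    libraries = {}
    for i, e in enumerate(truth.ecotypes):
        g = truth.ecotype_genome(e.name)
        lib_spec = truth.library_spec(e.name)
        ref_like = sd.ReferenceTruth(genome=g, repeats=[], decoys=[], seed=seed)
        libraries[e.name] = sd.simulate_library(ref_like, [], lib_spec, seed, stream=100 + i)
    return PanelFixture(truth=truth, libraries=libraries, seed=seed)


@dataclass
class PanelResults:
    reference: GenomeSeq
    catalog: list[RepeatPair]
    snps: dict[str, list[eco.SnpCall]]
    sv_calls: dict[str, list[eco.StructuralVariantCall]]
    sv_carriers: dict[str, set[str]]  # SV key -> predominant carriers
    sv_trace: dict[str, set[str]]  # SV key -> substoichiometric carriers
    matrix: eco.SnpMatrix
    phylogeny: eco.PanelPhylogeny
    groups: dict[str, int]
    concordance: pd.DataFrame
    concordance_overall: float
    median_depth: dict[str, float]


def analyze_panel(
    reference: GenomeSeq,
    libraries: dict[str, object],
    min_support: int = jd.DEFAULT_MIN_SUPPORT,
    n_groups: int = 6,
    n_bootstrap: int = 100,
    seed: int = 0,
    insert_mean: int = sd.INSERT_MEAN,
    read_length: int = sd.READ_LENGTH,
) -> PanelResults:
    """Run the cross-ecotype analysis.

    ``libraries`` maps ecotype -> ReadLibrary or PlacementSet.  Junctions
    are clustered over the pooled panel so one cluster's support can be
    read out in every ecotype (predominant vs substoichiometric forms).
    """
    if len(libraries) < 3:
        raise ValueError("need at least three ecotypes")
    catalog = find_repeat_pairs(reference, flank_window=insert_mean)
    index = GenomeIndex(reference, k=read_length // 2)
    ref_codes = None
    from .align_core import encode

    ref_codes = encode(reference.sequence)
    placements: dict[str, PlacementSet] = {}
    depths: dict[str, np.ndarray] = {}
    snps: dict[str, list[eco.SnpCall]] = {}
    median_depth: dict[str, float] = {}
    for name, lib in sorted(libraries.items()):
        pl = lib if isinstance(lib, PlacementSet) else map_reads(lib, index)
        placements[name] = pl
        # high-confidence (<= 1 mismatch) view: junction-spanning reads that
        # bleed 2-3 mismatching bases across a breakpoint are excluded, so
        # small deletions read as clean coverage gaps and never mimic SNPs
        depth = coverage_track(pl, max_mismatches=1)
        depths[name] = depth
        median_depth[name] = float(np.median(depth))
        snps[name] = eco.call_snps(
            base_pileup(pl, max_mismatches=1), ref_codes,
            mask=_poorly_aligned_mask(depth, read_length),
        )
        log.info("ecotype %s: %d SNPs, median depth %.1f",
                 name, len(snps[name]), median_depth[name])

    clusters = jd.cluster_discordant(placements)
    selected = [
        c
        for c in clusters
        if max(c.support_by_library.values()) > min_support
    ]
    log.info("panel: %d clusters, %d above support threshold", len(clusters), len(selected))

    sv_calls: dict[str, list[eco.StructuralVariantCall]] = {}
    sv_carriers: dict[str, set[str]] = {}
    sv_trace: dict[str, set[str]] = {}
    for name in placements:
        ecotype_clusters = [
            c for c in selected if c.support_by_library.get(name, 0) > 0
        ]
        calls = eco.classify_svs(
            name, ecotype_clusters, depths[name], catalog, reference,
            median_depth=median_depth[name], insert_mean=insert_mean,
            read_length=read_length,
        )
        sv_calls[name] = calls
        for call in calls:
            key = _sv_key(call)
            if call.stoichiometry == "substoichiometric":
                sv_trace.setdefault(key, set()).add(name)
            else:
                sv_carriers.setdefault(key, set()).add(name)

    matrix = eco.build_snp_matrix(snps, depths, ref_codes)
    phylogeny = eco.build_phylogeny(matrix, n_bootstrap=n_bootstrap, seed=seed)
    groups = eco.assign_groups(phylogeny.tree, k=n_groups)
    concordance, overall = eco.concordance_report(sv_carriers, groups)
    return PanelResults(
        reference=reference, catalog=catalog, snps=snps, sv_calls=sv_calls,
        sv_carriers=sv_carriers, sv_trace=sv_trace, matrix=matrix,
        phylogeny=phylogeny, groups=groups, concordance=concordance,
        concordance_overall=overall, median_depth=median_depth,
    )


def _poorly_aligned_mask(depth: np.ndarray, read_length: int, near_zero: int = 1):
    """Intervals around zero-coverage runs where junction-spanning reads
    bleed a few mismatching bases and would mimic clustered SNPs."""
    from .formats_io import Interval

    low = depth <= near_zero
    out = []
    in_run = False
    s = 0
    for i, v in enumerate(low):
        if v and not in_run:
            in_run, s = True, i
        elif not v and in_run:
            in_run = False
            if i - s >= 2:
                out.append(Interval(max(0, s - read_length), min(len(depth), i + read_length)))
    if in_run and len(low) - s >= 2:
        out.append(Interval(max(0, s - read_length), len(depth)))
    return out


def _sv_key(call: eco.StructuralVariantCall, binsize: int = 150) -> str:
    b1 = call.breakpoint1.start // binsize
    b2 = call.breakpoint2.start // binsize if call.breakpoint2 else call.breakpoint1.end // binsize
    return f"{call.kind}:{b1}:{b2}:{call.repeat_name}"
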