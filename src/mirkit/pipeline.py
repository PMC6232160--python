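"""End-to-end orchestration: inputs -> candidates -> filters -> catalogue.

Stages run in a fixed order (homology search, hairpin excision + six-criterion
filter, locus clustering and naming, composition profiling, dual-mode target
prediction with consensus intersection and inhibition typing, conservation
calls, family phylogeny), each communicating through plain records so any
stage is independently runnable.  All thresholds live in
:class:`PipelineConfig` with the published defaults, every dropped candidate
is logged with the criterion that rejected it, and the same config + seed
reproduce the same report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import conservation as conservation_mod
from . import hairpin, homology, loci_composition, phylo, synthetic_data, targets
from .seqio import ReferenceMiRNA, SequenceRecord, Transcript, write_fasta, write_tsv

log = logging.getLogger("mirkit.pipeline")


@dataclass
class PipelineConfig:
    """All stage thresholds, defaulting to the published cut-offs."""

    evalue_cutoff: float = 10.0
    mfei_cutoff: float = -0.85
    mature_len: tuple[int, int] = (19, 25)
    ref_mismatch_max: int = 2
    duplex_mismatch_max: int = 5
    au_range: tuple[float, float] = (30.0, 70.0)
    locus_mismatch_lt: int = 2
    psr_expectation: float = 3.0
    tf_score_lt: float = 4.0
    conserve_score_gt: float = 50.0
    conserve_cov_gt: float = 50.0
    bootstrap_reps: int = 1000
    seed: int = 0
    engine: str = "vienna"
    window_flank: int = 120
    min_phylo_family: int = 4
    simulation: Optional[synthetic_data.SimulationConfig] = None

    def thresholds(self) -> hairpin.CriteriaThresholds:
        return hairpin.CriteriaThresholds(
            mature_len_min=self.mature_len[0],
            mature_len_max=self.mature_len[1],
            ref_mismatch_max=self.ref_mismatch_max,
            duplex_mismatch_max=self.duplex_mismatch_max,
            au_min=self.au_range[0],
            au_max=self.au_range[1],
            mfei_cutoff=self.mfei_cutoff,
        )


def config_self_test(cfg: PipelineConfig) -> None:
    """Assert that the config defaults equal the published thresholds."""
    published = {
        "evalue_cutoff": 10.0,
        "mfei_cutoff": -0.85,
        "mature_len": (19, 25),
        "ref_mismatch_max": 2,
        "duplex_mismatch_max": 5,
        "au_range": (30.0, 70.0),
        "locus_mismatch_lt": 2,
        "psr_expectation": 3.0,
        "tf_score_lt": 4.0,
        "conserve_score_gt": 50.0,
        "conserve_cov_gt": 50.0,
        "bootstrap_reps": 1000,
    }
    defaults = PipelineConfig()
    for key, value in published.items():
        actual = getattr(defaults, key)
        if actual != value:
            raise AssertionError(f"default {key}={actual!r} != published {value!r}")
    _ = cfg  # the instance itself may deviate deliberately


@dataclass
class Candidate:
    """A homology-derived precursor candidate with its filter outcome."""

    candidate_id: str
    transcript_id: str
    tissue: str
    family: str
    reference_name: str
    precursor_interval: tuple[int, int]  # on the transcript, 1-based closed
    precursor_sequence: str
    mature_sequence: Optional[str]
    report: hairpin.FilterReport
    metrics: hairpin.HairpinMetrics
    site: Optional[hairpin.MatureSite]
    assigned_name: Optional[str] = None

    @property
    def accepted(self) -> bool:
        return self.report.accepted


@dataclass
class RunReport:
    funnel: dict = field(default_factory=dict)
    candidates: list = field(default_factory=list)
    loci: list = field(default_factory=list)
    locus_table: Optional[pd.DataFrame] = None
    tissue_tally: Optional[dict] = None
    composition: Optional[loci_composition.CompositionProfile] = None
    consensus_targets: list = field(default_factory=list)
    inhibition_counts: dict = field(default_factory=dict)
    targets_per_family: Optional[pd.DataFrame] = None
    conservation: Optional[dict] = None
    newick: Optional[str] = None
    names: dict = field(default_factory=dict)
    catalogue_stats: dict = field(default_factory=dict)
    dropped: list = field(default_factory=list)  # (candidate_id, reason)


class StageError(RuntimeError):
    def __init__(self, stage: str, record: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed at record {record!r}: {cause}")
        self.stage, self.record = stage, record


# ---------------------------------------------------------------------------
# stage: homology candidates


def find_candidates(
    refs: list[ReferenceMiRNA],
    transcripts: list[Transcript],
    cfg: PipelineConfig,
) -> list[Candidate]:
    """Best-hit homology search + hairpin excision + six-criterion filter."""
    db_len = sum(len(t.sequence) for t in transcripts)
    by_id = {t.id: t for t in transcripts}
    hits = []
    for ref in refs:
        ref_hits = []
        for tr in transcripts:
            hit = homology.local_align(
                ref.precursor.sequence, tr.sequence,
                query_id=ref.name, subject_id=tr.id,
            )
            if hit is None:
                continue
            ref_hits.append(homology.with_evalue(hit, len(ref.precursor.sequence), db_len))
        hits.extend(ref_hits)
    best = homology.best_hits(hits, evalue_cutoff=cfg.evalue_cutoff)

    ref_by_name = {r.name: r for r in refs}
    # criterion 2 compares against the prediction-reference species' matures
    matures_by_family: dict[str, list] = {}
    for r in refs:
        if r.homolog_of is None:
            matures_by_family.setdefault(r.family, []).extend(
                m.sequence for m in r.matures
            )
    thresholds = cfg.thresholds()
    candidates: list[Candidate] = []
    for k, (qid, hit) in enumerate(sorted(best.items())):
        ref = ref_by_name[qid]
        tr = by_id[hit.subject_id]
        fam_matures = matures_by_family.get(ref.family)
        if not fam_matures:
            continue
        cand = _evaluate_hit_region(ref, tr, hit, fam_matures, thresholds, cfg, f"cand_{k:04d}")
        if cand is not None:
            candidates.append(cand)
    return candidates


def _evaluate_hit_region(
    ref: ReferenceMiRNA,
    tr: Transcript,
    hit: homology.AlignmentHit,
    family_matures: list[str],
    thresholds: hairpin.CriteriaThresholds,
    cfg: PipelineConfig,
    candidate_id: str,
) -> Optional[Candidate]:
    seq = tr.sequence
    lo = max(1, hit.subject_start - cfg.window_flank)
    hi = min(len(seq), hit.subject_end + cfg.window_flank)
    window = seq[lo - 1 : hi]

    import edlib

    # anchor: closest family mature inside the hit window
    anchor = None
    for mat in family_matures:
        res = edlib.align(mat, window, mode="HW", task="locations", k=10)
        if res["editDistance"] == -1:
            continue
        if anchor is None or res["editDistance"] < anchor[0]:
            anchor = (res["editDistance"], res["locations"][0])
    if anchor is None:
        return None
    m_lo, m_hi = anchor[1]
    exc = hairpin.excise_precursor(
        window, m_lo + 1, m_hi + 1, engine=cfg.engine
    )
    if exc is None:
        return None
    p_start, p_end, structure = exc
    prec_seq = window[p_start - 1 : p_end]
    try:
        metrics = hairpin.compute_metrics(structure)
    except ValueError:
        return None
    site = hairpin.locate_best_mature(prec_seq, structure, family_matures)
    mature_seq = None
    mature_len = len(family_matures[0])
    if site is not None:
        mature_seq = prec_seq[site.start - 1 : site.end]
        mature_len = site.length
    report = hairpin.evaluate_criteria(metrics, site, mature_len, thresholds)
    return Candidate(
        candidate_id=candidate_id,
        transcript_id=tr.id,
        tissue=tr.tissue,
        family=ref.family,
        reference_name=ref.homolog_of or ref.name,
        precursor_interval=(lo + p_start - 1, lo + p_end - 1),
        precursor_sequence=prec_seq,
        mature_sequence=mature_seq,
        report=report,
        metrics=metrics,
        site=site,
    )


# ---------------------------------------------------------------------------
# full run


def run(cfg: PipelineConfig, outdir: Optional[Path] = None) -> RunReport:
    """Execute every stage on synthetic (or pre-loaded) inputs.

    With ``cfg.simulation`` set, the generator provides reference set,
    transcriptomes, target mRNAs and homolog sets with ground truth; the
    report gains an evaluation against that truth.
    """
    config_self_test(cfg)
    report = RunReport()
    if cfg.simulation is None:
        raise ValueError("run() currently requires cfg.simulation (or use run_on_data)")
    sim = cfg.simulation
    rng = np.random.default_rng(sim.seed)
    transcripts, manifest, refs = synthetic_data.simulate_transcriptome(sim, rng=rng)
    report.manifest = manifest
    return run_on_data(cfg, refs, transcripts, report=report, rng=rng)


def run_on_data(
    cfg: PipelineConfig,
    refs: list[ReferenceMiRNA],
    transcripts: list[Transcript],
    target_mrnas: Optional[list[Transcript]] = None,
    homolog_sets: Optional[dict] = None,
    report: Optional[RunReport] = None,
    rng: Optional[np.random.Generator] = None,
    outdir: Optional[Path] = None,
) -> RunReport:
    report = report or RunReport()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    # --- candidates & filtering
    try:
        candidates = find_candidates(refs, transcripts, cfg)
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("homology", "-", exc) from exc
    report.candidates = candidates
    accepted = [c for c in candidates if c.accepted]
    for c in candidates:
        if not c.accepted:
            reasons = ",".join(c.report.failed_criteria())
            report.dropped.append((c.candidate_id, reasons))
            log.info("dropped %s (%s) on %s", c.candidate_id, c.transcript_id, reasons)

    report.funnel = {
        "transcripts": len(transcripts),
        "candidates": len(candidates),
        "accepted": len(accepted),
    }

    # --- loci, names, tissues, composition
    members = [
        loci_composition.CandidateMember(
            c.candidate_id, c.precursor_sequence, c.mature_sequence or "",
            c.family, c.reference_name, c.tissue,
        )
        for c in accepted
    ]
    loci = loci_composition.cluster_loci(members, mismatch_lt=cfg.locus_mismatch_lt)
    report.loci = loci
    report.funnel["loci"] = len(loci)
    report.locus_table = loci_composition.locus_table(loci)
    names: dict[str, str] = {}
    for locus in loci:
        names.update(loci_composition.assign_names(locus))
    report.names = names
    for c in accepted:
        c.assigned_name = names.get(c.candidate_id)
    report.tissue_tally = loci_composition.tissue_tally(loci)
    matures = [c.mature_sequence for c in accepted if c.mature_sequence]
    if matures:
        report.composition = loci_composition.composition_profile(matures)
        report.catalogue_stats = loci_composition.catalogue_statistics(
            matures, [c.precursor_sequence for c in accepted]
        )

    # --- targets
    accepted_mature_records = [
        SequenceRecord(names.get(c.candidate_id, c.candidate_id), c.mature_sequence)
        for c in accepted
        if c.mature_sequence
    ]
    fam_of_mirna = {
        names.get(c.candidate_id, c.candidate_id): c.family
        for c in accepted
        if c.mature_sequence
    }
    if target_mrnas is None and cfg.simulation is not None and accepted_mature_records:
        target_mrnas, site_truth = synthetic_data.simulate_targets(
            accepted_mature_records, cfg.simulation, rng=rng
        )
        if hasattr(report, "manifest"):
            report.manifest.target_sites = site_truth
    consensus: list[targets.ConsensusHit] = []
    if target_mrnas and accepted_mature_records:
        for mir in accepted_mature_records:
            for mr in target_mrnas:
                psr = targets.scan_transcript(
                    mir, mr, "psrnatarget_like", cfg.psr_expectation
                )
                tf = targets.scan_transcript(
                    mir, mr, "targetfinder_like", cfg.tf_score_lt
                )
                consensus.extend(targets.intersect_modes(psr, tf))
    report.consensus_targets = consensus
    report.funnel["consensus_targets"] = len(consensus)
    inh = {"cleavage": 0, "translation": 0}
    for h in consensus:
        inh[h.inhibition] += 1
    report.inhibition_counts = inh
    fam_counts: dict[str, int] = {}
    for h in consensus:
        fam = fam_of_mirna.get(h.mirna_id, "unknown")
        fam_counts[fam] = fam_counts.get(fam, 0) + 1
    report.targets_per_family = pd.DataFrame(
        sorted(fam_counts.items()), columns=["family", "n_targets"]
    )

    # --- conservation
    if homolog_sets is None and cfg.simulation is not None and target_mrnas:
        homolog_sets, conserved_truth = synthetic_data.simulate_homolog_sets(
            target_mrnas, rng
        )
        report.conserved_truth = conserved_truth
    if homolog_sets is not None and consensus:
        fam_by_mrna = {}
        for h in consensus:
            fam_by_mrna.setdefault(h.transcript_id, fam_of_mirna.get(h.mirna_id, "unknown"))
        mrna_by_id = {t.id: t for t in (target_mrnas or [])}
        calls = []
        for tid, fam in sorted(fam_by_mrna.items()):
            tr = mrna_by_id.get(tid)
            if tr is None:
                continue
            calls.append(
                conservation_mod.classify_conserved(
                    tr.record, homolog_sets, family=fam,
                    score_gt=cfg.conserve_score_gt, coverage_gt=cfg.conserve_cov_gt,
                )
            )
        report.conservation = conservation_mod.summarize_by_family(calls)
        report.conservation["calls"] = calls

    # --- phylogeny of the largest family
    fam_groups: dict[str, list[Candidate]] = {}
    for c in accepted:
        fam_groups.setdefault(c.family, []).append(c)
    big = [g for g in fam_groups.values() if len(g) >= cfg.min_phylo_family]
    if big:
        group = max(big, key=lambda g: (len(g), g[0].family))
        recs = [
            SequenceRecord(names.get(c.candidate_id, c.candidate_id), c.precursor_sequence)
            for c in group
        ]
        # precursors in a family can be identical alleles; NJ needs >= 3 distinct
        uniq: dict[str, SequenceRecord] = {}
        for r in recs:
            uniq.setdefault(r.sequence, r)
        if len(uniq) >= 3:
            ids, rows = phylo.progressive_align(list(uniq.values()))
            try:
                tree = phylo.bootstrap(
                    ids, rows, replicates=cfg.bootstrap_reps, seed=cfg.seed
                )
                report.newick = tree.to_newick()
            except ValueError:
                report.newick = None

    if outdir is not None:
        write_artifacts(report, refs, transcripts, outdir)
    return report


# ---------------------------------------------------------------------------
# truth evaluation & summaries


def evaluate_against_truth(report: RunReport, manifest) -> dict:
    """Recall/precision of the filter stage against the implant manifest."""
    implanted_ids = {t.transcript_id for t in manifest.implanted}
    accepted = [c for c in report.candidates if c.accepted]
    recovered = set()
    for c in accepted:
        if c.transcript_id in implanted_ids:
            truth = next(t for t in manifest.implanted if t.transcript_id == c.transcript_id)
            lo, hi = truth.precursor_interval
            if min(hi, c.precursor_interval[1]) >= max(lo, c.precursor_interval[0]):
                recovered.add(c.transcript_id)
    decoy_accepts = [c for c in accepted if c.transcript_id in set(manifest.decoy_ids)]
    recall = len(recovered) / len(implanted_ids) if implanted_ids else float("nan")
    return {
        "n_implants": len(implanted_ids),
        "n_recovered": len(recovered),
        "recall": recall,
        "n_decoy_accepts": len(decoy_accepts),
        "decoy_accept_ids": [c.transcript_id for c in decoy_accepts],
    }


def evaluate_targets_against_truth(report: RunReport, manifest) -> dict:
    """Designed-site recovery and inhibition-label agreement."""
    truth = {(t.mirna_id, t.mrna_id): t for t in manifest.target_sites}
    found = {}
    for h in report.consensus_targets:
        found[(h.mirna_id, h.transcript_id)] = h
    reportable = {
        k: t
        for k, t in truth.items()
        if t.designed_penalty <= 3.0  # consensus requires passing both modes
    }
    recovered = 0
    inhibition_agree = 0
    for k, t in reportable.items():
        h = found.get(k)
        if h is None:
            continue
        lo, hi = t.site_interval
        if min(hi, h.site_end) >= max(lo, h.site_start):
            recovered += 1
            if h.inhibition == t.designed_inhibition:
                inhibition_agree += 1
    return {
        "n_designed_consensus": len(reportable),
        "n_recovered": recovered,
        "site_recall": recovered / len(reportable) if reportable else float("nan"),
        "inhibition_agreement": (
            inhibition_agree / recovered if recovered else float("nan")
        ),
    }


def summarize(report: RunReport) -> str:
    """Human-readable stage funnel and headline tables."""
    lines = ["stage funnel:"]
    for k, v in report.funnel.items():
        lines.append(f"  {k:>20}: {v}")
    if report.locus_table is not None and len(report.locus_table):
        lines.append("loci per family:")
        for _, row in report.locus_table.iterrows():
            lines.append(f"  {row['family']:>10}: {row['n_loci']} loci, {row['n_members']} members")
    if report.tissue_tally:
        pct = report.tissue_tally["percent"]
        lines.append(
            "tissue occupancy (%): "
            + ", ".join(f"{t}={pct[t]:.1f}" for t in sorted(pct))
        )
    inh = report.inhibition_counts
    if inh:
        lines.append(
            f"inhibition split: cleavage={inh.get('cleavage', 0)} "
            f"translation={inh.get('translation', 0)}"
        )
    if report.conservation:
        lines.append(
            f"conserved targets: {report.conservation['conserved_total']} "
            f"({report.conservation['conserved_percent']:.2f}%), "
            f"novel: {report.conservation['novel_total']}"
        )
    if report.newick:
        lines.append(f"family tree: {report.newick}")
    return "\n".join(lines)


def write_artifacts(report: RunReport, refs, transcripts, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    accepted = [c for c in report.candidates if c.accepted]
    if accepted:
        write_fasta(
            [
                SequenceRecord(c.assigned_name or c.candidate_id, c.precursor_sequence)
                for c in accepted
            ],
            outdir / "accepted_precursors.fasta",
        )
    rows = [
        {
            "candidate_id": c.candidate_id,
            "name": c.assigned_name,
            "transcript_id": c.transcript_id,
            "family": c.family,
            "tissue": c.tissue,
            "start": c.precursor_interval[0],
            "end": c.precursor_interval[1],
            "mfe": c.metrics.mfe,
            "amfe": c.metrics.amfe,
            "mfei": c.metrics.mfei,
            "au_percent": c.metrics.au_percent,
            "accepted": c.accepted,
            "failed": ",".join(c.report.failed_criteria()) or ".",
        }
        for c in report.candidates
    ]
    if rows:
        write_tsv(rows, outdir / "candidates.tsv")
    hit_rows = [
        {
            "mirna_id": h.mirna_id,
            "transcript_id": h.transcript_id,
            "start": h.site_start,
            "end": h.site_end,
            "expectation_psr": h.psr_expectation,
            "score_tf": h.tf_score,
            "inhibition": h.inhibition,
            "cleavage_pos": h.cleavage_position,
        }
        for h in report.consensus_targets
    ]
    if hit_rows:
        write_tsv(hit_rows, outdir / "consensus_targets.tsv")
    if report.newick:
        (outdir / "family_tree.nwk").write_text(report.newick + "\n")
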