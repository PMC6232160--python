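"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:

* a reference set of miRNA families (miRBase-style names, rice-like species
  code) whose matures follow the published length distribution over
  20/21/22 nt (7.8% / 85.8% / 6.4%) and a strong 5'-uridine preference;
* tissue-labelled transcriptomes made of decoy transcripts plus implant
  transcripts, each embedding one constructed pre-miRNA hairpin that passes
  the six hairpin criteria by construction (verified by folding, with
  rejection sampling);
* decoys of three classes, each designed to exercise a different filter:
  uniform-random background, dinucleotide-resampled (Markov) shuffles of
  implant precursors (hairpin destroyed, composition kept), and weakly
  folding A/U-stem inverted repeats;
* target mRNAs carrying one complementary site per mRNA with a designed
  penalty under the duplex scorer, labelled cleavage- or translation-type
  by whether a mismatch was forced at miRNA position 10/11.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import hairpin, targets
from .seqio import ReferenceMiRNA, SequenceRecord, Transcript, reverse_complement

BASES = "ACGU"

# published tissue shares of mature miRNAs (root 31.9%, culm 26.2%,
# bud 22.7%, leaf 19.1%), used as sampling weights
DEFAULT_TISSUE_WEIGHTS = {"bud": 0.227, "culm": 0.262, "leaf": 0.191, "root": 0.320}

DEFAULT_MATURE_LENGTH_DIST = {20: 0.078, 21: 0.858, 22: 0.064}

# reference loci per family, shaped like the rice annotation of the 14
# families (94 loci in total)
DEFAULT_FAMILY_LOCI = {
    "MIR156": 12, "MIR160": 6, "MIR166": 13, "MIR167": 10, "MIR169": 18,
    "MIR171": 9, "MIR172": 4, "MIR319": 2, "MIR393": 2, "MIR396": 8,
    "MIR444": 6, "MIR529": 2, "MIR827": 1, "MIR1430": 1,
}


class GenerationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 0
    n_families: int = 14
    family_loci: dict = field(default_factory=lambda: dict(DEFAULT_FAMILY_LOCI))
    # extra query species: orthologs of every reference locus join the
    # homology query set (emulating a multi-species precursor collection
    # with one species as prediction reference)
    query_species: tuple = ("zma", "sbi", "bdi")
    ortholog_divergence: tuple[int, int] = (0, 2)  # substitutions vs reference mature
    n_decoys: int = 60
    n_implants: int = 50
    decoy_length_range: tuple[int, int] = (200, 600)
    gc_target: float = 0.5
    mature_length_dist: dict = field(default_factory=lambda: dict(DEFAULT_MATURE_LENGTH_DIST))
    loop_length_range: tuple[int, int] = (4, 12)
    duplex_mismatch_range: tuple[int, int] = (0, 4)
    stem_extension_range: tuple[int, int] = (8, 60)
    u5_fraction: float = 0.85
    tissue_weights: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_WEIGHTS))
    n_target_mrnas: int = 40
    target_length_range: tuple[int, int] = (300, 800)
    target_penalty_levels: list = field(default_factory=lambda: [0.0, 0.5, 1.0, 2.0, 3.0, 3.5])
    retry_cap: int = 100
    engine: str = "vienna"

    def validate(self) -> None:
        for name in ("n_families", "n_decoys", "n_implants", "n_target_mrnas"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "decoy_length_range",
            "loop_length_range",
            "duplex_mismatch_range",
            "stem_extension_range",
            "target_length_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered, got ({lo}, {hi})")
        for name in ("mature_length_dist", "tissue_weights"):
            total = sum(getattr(self, name).values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} weights must sum to 1, got {total}")
        if any(lv < 0 for lv in self.target_penalty_levels):
            raise ValueError("target penalty levels must be non-negative")


@dataclass
class ImplantTruth:
    transcript_id: str
    precursor_interval: tuple[int, int]  # 1-based closed on the transcript
    mature_interval: tuple[int, int]
    arm: str
    family: str
    tissue: str
    reference_name: str
    mature_sequence: str
    retries: int = 0


@dataclass
class TargetSiteTruth:
    mrna_id: str
    mirna_id: str
    site_interval: tuple[int, int]
    designed_penalty: float
    designed_inhibition: str


@dataclass
class TruthManifest:
    implanted: list = field(default_factory=list)
    decoy_ids: list = field(default_factory=list)
    decoy_classes: dict = field(default_factory=dict)  # id -> class label
    target_sites: list = field(default_factory=list)

    def implant_rows(self) -> list[dict]:
        return [
            {
                "transcript_id": t.transcript_id,
                "precursor_start": t.precursor_interval[0],
                "precursor_end": t.precursor_interval[1],
                "mature_start": t.mature_interval[0],
                "mature_end": t.mature_interval[1],
                "arm": t.arm,
                "family": t.family,
                "tissue": t.tissue,
                "reference_name": t.reference_name,
                "mature_sequence": t.mature_sequence,
            }
            for t in self.implanted
        ]


# ---------------------------------------------------------------------------
# small helpers


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(BASES), size=length, p=p))


_NONPAIRING = {"A": "ACG", "C": "ACU", "G": "AG", "U": "CU"}


def _mutate_star(star: str, mature: str, n_mismatches: int, rng: np.random.Generator) -> str:
    """Substitute star positions so they can pair with neither WC nor G:U."""
    L = len(mature)
    pos = rng.choice(L, size=n_mismatches, replace=False)
    star_list = list(star)
    for k in pos:
        # star index pairing mature position k is L-1-k
        j = L - 1 - k
        star_list[j] = rng.choice(list(_NONPAIRING[mature[k]]))
    return "".join(star_list)


def _random_mature(rng: np.random.Generator, cfg: SimulationConfig) -> str:
    lengths = sorted(cfg.mature_length_dist)
    probs = [cfg.mature_length_dist[l] for l in lengths]
    L = int(rng.choice(lengths, p=probs))
    seq = list(_random_seq(rng, L, cfg.gc_target))
    if rng.random() < cfg.u5_fraction:
        seq[0] = "U"
    elif seq[0] == "U":
        seq[0] = rng.choice(list("ACG"))
    return "".join(seq)


# ---------------------------------------------------------------------------
# precursor construction


def build_precursor(
    mature: str | SequenceRecord,
    loop_length: int,
    duplex_mismatches: int,
    rng: np.random.Generator,
    arm: Optional[str] = None,
    stem_extension: int = 20,
    flank: tuple[int, int] = (3, 3),
) -> tuple[str, tuple[int, int], tuple[int, int], str]:
    """Assemble one hairpin precursor around a mature sequence.

    Layout (5'->3'): flank + lower-stem + arm + loop + arm + lower-stem' +
    flank, where the arm opposite the mature is its reverse complement with
    exactly ``duplex_mismatches`` non-pairing substitutions placed uniformly
    at random, and the lower stem extends the duplex so precursors reach
    realistic lengths.  Returns (sequence, mature_interval, star_interval,
    arm) with 1-based closed intervals.
    """
    m = mature.sequence if isinstance(mature, SequenceRecord) else mature
    if not 19 <= len(m) <= 25:
        raise ValueError(f"mature length {len(m)} outside 19-25 nt")
    if loop_length < 3:
        raise ValueError("loop length must be >= 3")
    if duplex_mismatches > 5:
        raise ValueError("no more than five duplex mismatches are allowed")
    if set(m) - set(BASES):
        raise ValueError("mature contains ambiguity codes")
    if arm is None:
        arm = str(rng.choice(["5p", "3p"]))

    star = _mutate_star(reverse_complement(m), m, duplex_mismatches, rng)
    loop = "".join(rng.choice(list("ACU"), size=loop_length, p=[0.5, 0.4, 0.1]))
    ext5 = _random_seq(rng, stem_extension, 0.5)
    ext3 = reverse_complement(ext5)
    f5 = "".join(rng.choice(list("AC"), size=flank[0]))
    f3 = "".join(rng.choice(list("AC"), size=flank[1]))

    if arm == "5p":
        arm5, arm3 = m, star
    else:
        arm5, arm3 = star, m
    seq = f5 + ext5 + arm5 + loop + arm3 + ext3 + f3
    a5_start = len(f5) + len(ext5) + 1
    a3_start = a5_start + len(arm5) + loop_length
    if arm == "5p":
        mat_iv = (a5_start, a5_start + len(m) - 1)
        star_iv = (a3_start, a3_start + len(star) - 1)
    else:
        star_iv = (a5_start, a5_start + len(star) - 1)
        mat_iv = (a3_start, a3_start + len(m) - 1)
    return seq, mat_iv, star_iv, arm


def build_validated_precursor(
    mature: str,
    reference_mature: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[str, tuple[int, int], str, int]:
    """Build a precursor that passes all six hairpin criteria, with retries.

    Folds each construction with the configured engine and re-evaluates the
    full filter; regenerates (new loop/extension/mismatch placement) up to
    the retry cap, returning the retry count.  Raises GenerationError when
    the cap is exhausted.
    """
    for attempt in range(cfg.retry_cap):
        loop_len = int(rng.integers(cfg.loop_length_range[0], cfg.loop_length_range[1] + 1))
        dmm = int(rng.integers(cfg.duplex_mismatch_range[0], cfg.duplex_mismatch_range[1] + 1))
        ext = int(rng.integers(cfg.stem_extension_range[0], cfg.stem_extension_range[1] + 1))
        seq, mat_iv, _, arm = build_precursor(
            mature, loop_len, dmm, rng, stem_extension=ext
        )
        try:
            st = hairpin.fold(seq, engine=cfg.engine)
        except hairpin.FoldError:
            continue
        metrics = hairpin.compute_metrics(st)
        site = hairpin.locate_mature(seq, st, reference_mature)
        report = hairpin.evaluate_criteria(metrics, site, len(mature))
        if report.accepted:
            return seq, mat_iv, arm, attempt
    raise GenerationError(
        f"could not build an accepted precursor in {cfg.retry_cap} tries"
    )


# ---------------------------------------------------------------------------
# reference set


def make_reference_set(cfg: SimulationConfig, rng: np.random.Generator) -> list[ReferenceMiRNA]:
    """A synthetic rice-like reference set, several loci per family.

    Loci within a family share a base mature diverged by up to three
    substitutions (paralogs), each wrapped in its own validated precursor.
    """
    # canonical family ordering (numeric where the names allow)
    families = sorted(cfg.family_loci, key=lambda f: (len(f), f))
    if cfg.n_families:
        families = families[: cfg.n_families]
    refs: list[ReferenceMiRNA] = []
    for fam in families:
        base = _random_mature(rng, cfg)
        for v in range(cfg.family_loci[fam]):
            variant = chr(ord("a") + v % 26)
            mature = base
            n_sub = 0 if v == 0 else int(rng.integers(1, 4))
            for _ in range(n_sub):
                k = int(rng.integers(len(mature)))
                mature = (
                    mature[:k]
                    + str(rng.choice(sorted(set(BASES) - {mature[k]})))
                    + mature[k + 1:]
                )
            seq, _, _, _ = build_validated_precursor(mature, mature, cfg, rng)
            suffix = variant if v < 26 else f"{variant}{v // 26}"
            name = f"osa-{fam}{suffix}"
            refs.append(
                ReferenceMiRNA(
                    name=name,
                    family=fam,
                    species_code="osa",
                    precursor=SequenceRecord(name, seq),
                    matures=[SequenceRecord(name.replace("MIR", "miR"), mature)],
                )
            )
            # orthologs of this locus in the extra query species
            for sp in cfg.query_species:
                om = mature
                lo, hi = cfg.ortholog_divergence
                for _ in range(int(rng.integers(lo, hi + 1))):
                    k = int(rng.integers(len(om)))
                    om = om[:k] + str(rng.choice(sorted(set(BASES) - {om[k]}))) + om[k + 1:]
                oseq, _, _, _ = build_validated_precursor(om, om, cfg, rng)
                oname = f"{sp}-{fam}{suffix}"
                refs.append(
                    ReferenceMiRNA(
                        name=oname,
                        family=fam,
                        species_code=sp,
                        precursor=SequenceRecord(oname, oseq),
                        matures=[SequenceRecord(oname.replace("MIR", "miR"), om)],
                        homolog_of=name,
                    )
                )
    return refs


# ---------------------------------------------------------------------------
# decoys


def _markov_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Resample a sequence from its own first-order (dinucleotide) model."""
    trans: dict[str, list[str]] = {b: [] for b in BASES}
    for a, b in zip(seq, seq[1:]):
        trans[a].append(b)
    out = [seq[0]]
    for _ in range(len(seq) - 1):
        nxt = trans.get(out[-1]) or list(BASES)
        out.append(nxt[int(rng.integers(len(nxt)))])
    return "".join(out)


def _au_inverted_repeat(rng: np.random.Generator, length: int) -> str:
    """A weakly folding decoy: A/U-only stem inside GC-balanced background."""
    stem = "".join(rng.choice(list("AU"), size=25))
    loop = _random_seq(rng, 8, 0.5)
    mid = stem + loop + reverse_complement(stem)
    pad = max(0, length - len(mid))
    left = _random_seq(rng, pad // 2, 0.65)
    right = _random_seq(rng, pad - pad // 2, 0.65)
    return left + mid + right


# ---------------------------------------------------------------------------
# transcriptome simulation


def _sample_tissue(rng: np.random.Generator, weights: dict) -> str:
    names = sorted(weights)
    p = np.array([weights[n] for n in names])
    return str(rng.choice(names, p=p / p.sum()))


def simulate_transcriptome(
    cfg: SimulationConfig,
    refs: Optional[list[ReferenceMiRNA]] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[Transcript], TruthManifest, list[ReferenceMiRNA]]:
    """Decoy transcripts plus implant transcripts with ground-truth manifest.

    Implants embed a validated precursor built around a (possibly 1-sub
    variant of a) reference mature inside random flanks.  Decoys cycle
    through the three decoy classes.  Fully reproducible from cfg.seed.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if refs is None:
        refs = make_reference_set(cfg, rng)

    transcripts: list[Transcript] = []
    manifest = TruthManifest()

    # implants are anchored to distinct prediction-reference loci while
    # possible (ortholog queries only help recover them)
    anchors = [k for k, r in enumerate(refs) if r.homolog_of is None]
    if cfg.n_implants <= len(anchors):
        ref_choice = [anchors[int(k)] for k in rng.permutation(len(anchors))[: cfg.n_implants]]
    else:
        reps = cfg.n_implants // len(anchors) + 1
        pool = np.concatenate([rng.permutation(len(anchors)) for _ in range(reps)])
        ref_choice = [anchors[int(k)] for k in pool[: cfg.n_implants]]
    for i in range(cfg.n_implants):
        ref = refs[int(ref_choice[i])]
        ref_mat = ref.matures[0].sequence
        mature = ref_mat
        n_sub = int(rng.integers(0, 2))  # 0-1 substitutions vs reference
        if n_sub:
            k = int(rng.integers(len(mature)))
            mature = mature[:k] + str(rng.choice(sorted(set(BASES) - {mature[k]}))) + mature[k + 1:]
        prec, mat_iv, arm, retries = build_validated_precursor(mature, ref_mat, cfg, rng)
        lo, hi = cfg.decoy_length_range
        flank_total = max(40, int(rng.integers(lo, hi + 1)) - len(prec))
        f5 = int(rng.integers(10, max(11, flank_total - 10)))
        left = _random_seq(rng, f5, cfg.gc_target)
        right = _random_seq(rng, flank_total - f5, cfg.gc_target)
        seq = left + prec + right
        tid = f"implant_{i:04d}"
        tissue = _sample_tissue(rng, cfg.tissue_weights)
        transcripts.append(Transcript(SequenceRecord(tid, seq), tissue))
        off = len(left)
        manifest.implanted.append(
            ImplantTruth(
                transcript_id=tid,
                precursor_interval=(off + 1, off + len(prec)),
                mature_interval=(off + mat_iv[0], off + mat_iv[1]),
                arm=arm,
                family=ref.family,
                tissue=tissue,
                reference_name=ref.name,
                mature_sequence=mature,
                retries=retries,
            )
        )

    decoy_classes = ["random", "shuffled_implant", "au_repeat"]
    for i in range(cfg.n_decoys):
        cls = decoy_classes[i % len(decoy_classes)]
        length = int(rng.integers(cfg.decoy_length_range[0], cfg.decoy_length_range[1] + 1))
        if cls == "random":
            seq = _random_seq(rng, length, cfg.gc_target)
        elif cls == "shuffled_implant" and manifest.implanted:
            src = manifest.implanted[i % len(manifest.implanted)]
            src_tr = transcripts[i % len(manifest.implanted)].sequence
            seq = _markov_shuffle(src_tr[:length] if len(src_tr) >= length else src_tr, rng)
        else:
            seq = _au_inverted_repeat(rng, length)
            cls = "au_repeat"
        tid = f"decoy_{i:04d}"
        tissue = _sample_tissue(rng, cfg.tissue_weights)
        transcripts.append(Transcript(SequenceRecord(tid, seq), tissue))
        manifest.decoy_ids.append(tid)
        manifest.decoy_classes[tid] = cls

    return transcripts, manifest, refs


# ---------------------------------------------------------------------------
# target mRNA simulation


def _design_site(
    mirna: str, level: float, rng: np.random.Generator, translation: bool
) -> Optional[str]:
    """A site whose duplex penalty equals ``level`` under the scorer.

    Edits avoid the miRNA terminal positions so the windowed and full-length
    modes score identically.  Returns None when the level cannot be composed
    for this miRNA (e.g. no G/U available for a 0.5 wobble step).
    """
    L = len(mirna)
    site = list(reverse_complement(mirna))  # site[j] faces miRNA position L-j (1-based)

    def site_index(pos: int) -> int:
        return L - pos

    core_pos = [int(p) for p in rng.permutation(range(max(2, CORE_LO), CORE_HI + 1))]
    # keep the miRNA 3' terminal position intact
    outer_pos = [int(p) for p in rng.permutation(range(14, L - 1))]

    remaining = level
    used: set[int] = set()

    def apply_mismatch(pos: int) -> None:
        j = site_index(pos)
        site[j] = rng.choice(list(_NONPAIRING[mirna[pos - 1]]))
        used.add(pos)

    def apply_gu(pos: int) -> bool:
        b = mirna[pos - 1]
        j = site_index(pos)
        if b == "G":
            site[j] = "U"
        elif b == "U":
            site[j] = "G"
        else:
            return False
        used.add(pos)
        return True

    if translation:
        pos = int(rng.choice([10, 11]))
        if remaining < 2.0 - 1e-9:
            return None
        apply_mismatch(pos)
        remaining -= 2.0

    # 2.0 steps: core mismatches (avoiding 10/11 unless translation)
    for pos in core_pos:
        if remaining < 2.0 - 1e-9:
            break
        if pos in used or pos in (10, 11):
            continue
        apply_mismatch(pos)
        remaining -= 2.0
    # 1.0 steps: outer mismatches
    for pos in outer_pos:
        if remaining < 1.0 - 1e-9:
            break
        if pos in used:
            continue
        apply_mismatch(pos)
        remaining -= 1.0
    # 0.5 steps: outer G:U wobbles
    for pos in outer_pos:
        if remaining < 0.5 - 1e-9:
            break
        if pos in used:
            continue
        if apply_gu(pos):
            remaining -= 0.5
    if abs(remaining) > 1e-9:
        return None
    return "".join(site)


CORE_LO, CORE_HI = 3, 9  # core edit positions kept clear of 2 and 10-13 margins


def simulate_targets(
    mirnas: list[SequenceRecord],
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    translation_fraction: float = 0.15,
) -> tuple[list[Transcript], list[TargetSiteTruth]]:
    """Target mRNAs, one designed complementary site each.

    Penalty levels cycle through ``cfg.target_penalty_levels``; each site is
    verified against the duplex scorer (designed == scored within 1e-9).
    Sites with levels >= 2 become translation-type (mismatch forced at
    position 10/11) at the requested fraction.  Raises GenerationError
    naming the level when no miRNA can realise it.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    if not mirnas:
        return [], []
    mrnas: list[Transcript] = []
    truths: list[TargetSiteTruth] = []
    for i in range(cfg.n_target_mrnas):
        level = float(cfg.target_penalty_levels[i % len(cfg.target_penalty_levels)])
        translation = level >= 2.0 and rng.random() < translation_fraction
        order = rng.permutation(len(mirnas))
        site = None
        chosen = None
        for idx in order:
            chosen = mirnas[int(idx)]
            site = _design_site(chosen.sequence, level, rng, translation)
            if site is not None:
                break
        if site is None:
            raise GenerationError(f"penalty level {level} is not achievable for any miRNA")
        length = int(rng.integers(cfg.target_length_range[0], cfg.target_length_range[1] + 1))
        pos = int(rng.integers(30, max(31, length - len(site) - 30)))
        background = _random_seq(rng, length, cfg.gc_target)
        seq = background[:pos] + site + background[pos + len(site):]
        tid = f"mrna_{i:04d}"
        sc = targets.score_duplex(chosen.sequence, site, "targetfinder_like")
        if abs(sc.expectation - level) > 1e-9:
            raise GenerationError(
                f"designed site for level {level} scored {sc.expectation}"
            )
        inh = "translation" if translation else "cleavage"
        mrnas.append(Transcript(SequenceRecord(tid, seq), "unknown"))
        truths.append(
            TargetSiteTruth(tid, chosen.id, (pos + 1, pos + len(site)), level, inh)
        )
    return mrnas, truths


# ---------------------------------------------------------------------------
# cross-species homolog sets for conservation calls


def simulate_homolog_sets(
    target_mrnas: list[Transcript],
    rng: np.random.Generator,
    species: tuple[str, ...] = ("osa", "zma", "ath", "vvi"),
    conserved_fraction: float = 0.8,
    divergence: float = 0.08,
) -> tuple[dict, set]:
    """Per-species homolog sequence sets plus the set of conserved mRNA ids.

    A conserved target gets a mildly diverged full-length copy in every
    species; novel targets get none.
    """
    sets: dict[str, list[SequenceRecord]] = {sp: [] for sp in species}
    conserved: set[str] = set()
    for tr in target_mrnas:
        if rng.random() >= conserved_fraction:
            continue
        conserved.add(tr.id)
        for sp in species:
            seq = list(tr.sequence)
            n_mut = int(len(seq) * divergence)
            for k in rng.choice(len(seq), size=n_mut, replace=False):
                seq[k] = str(rng.choice(sorted(set(BASES) - {seq[k]})))
            sets[sp].append(SequenceRecord(f"{sp}_{tr.id}", "".join(seq)))
    return sets, conserved
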