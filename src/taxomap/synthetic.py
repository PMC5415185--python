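"""Synthetic mock-community fixtures with planted ground truth.

Generates everything the pipeline consumes — reference FASTA, taxonomy TSV,
one SAM file per database, and a sample context — from a declarative
:class:`CommunitySpec`.  Reads are placed at uniformly sampled positions with
an exact, scheduled number of substitutions per mate, and alignment scores
are synthesized as ``read_length - k * mismatches`` (monotone in edit
distance, which is all the method is sensitive to).  Because fragment counts,
mismatch schedules and tie structure are fixed by the spec, the expected
per-reference statistics and post-processing verdicts are available in closed
form (:func:`truth_from_spec`) and serve as an end-to-end oracle that never
touches the pipeline code.

Multi-mapped fragments are emulated by emitting an equal-score (or
score-offset) alignment of the same fragment onto a decoy reference in a
lower-priority database: the planted reference keeps the assignment through
the priority tie-break, but the fragment is no longer uniquely mapped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .hit_resolution import DatabaseSpec
from .reference_stats import SampleContext, s_abundance
from .taxonomy import TaxonomyPath, write_taxonomy_tsv

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def make_lineage(
    ref_name: str,
    species: tuple[int, str],
    genus: tuple[int, str],
    family: Optional[tuple[int, str]] = None,
    order: Optional[tuple[int, str]] = None,
    clazz: Optional[tuple[int, str]] = None,
    phylum: Optional[tuple[int, str]] = None,
    superkingdom: tuple[int, str] = (2, "Bacteria"),
    strain_taxid: Optional[int] = None,
) -> TaxonomyPath:
    """Build an 8-rank path; unspecified middle ranks are derived from the genus.

    The derived ranks get deterministic synthetic taxids (offsets of the genus
    taxid) so that clade collapsing by taxid is exercised at every level.
    """
    g_taxid, g_name = genus
    family = family or (g_taxid + 100000, g_name + "aceae")
    order = order or (g_taxid + 200000, g_name + "ales")
    clazz = clazz or (g_taxid + 300000, g_name + "ia")
    phylum = phylum or (g_taxid + 400000, g_name + "ota")
    slots = [
        (strain_taxid, ref_name),
        species,
        genus,
        family,
        order,
        clazz,
        phylum,
        superkingdom,
    ]
    return TaxonomyPath(tuple(s[0] for s in slots), tuple(s[1] for s in slots))


@dataclass(frozen=True)
class PlantedReference:
    """One reference with a planted read load.

    ``mismatches_per_read`` is applied cyclically over the emitted mate
    records, so the total edit distance is exact.  The first ``n_shared``
    fragments additionally hit ``decoy`` (db, ref) with SAS offset
    ``decoy_score_offset`` (0 = tie, making the fragment non-unique).
    """

    name: str
    db: str
    length_bp: int
    n_fragments: int
    lineage: TaxonomyPath
    mismatches_per_read: tuple[int, ...] = (0,)
    n_shared: int = 0
    decoy: Optional[tuple[str, str]] = None
    decoy_score_offset: int = 0
    violates: Optional[str] = None  # planted criterion label for contaminants

    def __post_init__(self) -> None:
        if self.n_fragments <= 0 or self.length_bp <= 0:
            raise ValueError("counts and lengths must be positive")
        if self.n_shared > self.n_fragments:
            raise ValueError("n_shared cannot exceed n_fragments")
        if self.n_shared and self.decoy is None:
            raise ValueError("shared fragments need a decoy reference")


@dataclass(frozen=True)
class CommunitySpec:
    """Declarative description of a synthetic sample and its databases."""

    references: tuple[PlantedReference, ...]
    databases: tuple[DatabaseSpec, ...]
    decoy_refs: tuple[tuple[str, str, int], ...] = ()  # (db, name, length_bp)
    read_length: int = 100
    insert_size: int = 300
    paired: bool = True
    total_clean_reads: int = 10000
    seed: int = 0
    score_per_mismatch: int = 5

    def __post_init__(self) -> None:
        db_names = {d.name for d in self.databases}
        for ref in self.references:
            if ref.db not in db_names:
                raise ValueError(f"reference {ref.name!r} placed in unknown database {ref.db!r}")
            span = self.insert_size if self.paired else self.read_length
            if span > ref.length_bp:
                raise ValueError(
                    f"fragment span {span} exceeds genome length {ref.length_bp} "
                    f"for reference {ref.name!r}"
                )
        if self.paired and self.insert_size < self.read_length:
            raise ValueError("insert size shorter than read length")

    @property
    def mates_per_fragment(self) -> int:
        return 2 if self.paired else 1


@dataclass(frozen=True)
class RefTruth:
    """Closed-form expected statistics for one planted reference."""

    ref_name: str
    db: str
    species: str
    read_count: int
    read_count_uniq: int
    nucleotides: int
    mismatches: int
    s_abundance: float
    r_abundance: float
    strain_failed: frozenset[str]


@dataclass(frozen=True)
class TruthTable:
    refs: dict[str, RefTruth]
    accepted_species: frozenset[str]
    rejected_species: dict[str, frozenset[str]]  # species name -> failed criteria


@dataclass(frozen=True)
class FixtureBundle:
    fasta_path: Path
    taxonomy_path: Path
    sam_paths: dict[str, Path]
    context: SampleContext
    truth: TruthTable
    spec: CommunitySpec


def _schedule_sum(schedule: Sequence[int], n_records: int) -> int:
    full, rem = divmod(n_records, len(schedule))
    return full * sum(schedule) + sum(schedule[:rem])


def truth_from_spec(
    spec: CommunitySpec,
    min_read_count: int = 10,
    max_mismatch_ratio: float = 0.01,
    min_s_abundance: float = 0.01,
    min_unique_fraction: float = 0.005,
) -> TruthTable:
    """Expected per-reference counts and verdicts, straight from arithmetic.

    Criteria are evaluated from the spec's planted numbers only (reads,
    sizes, schedules), independently of the classification pipeline, so the
    result is a genuine oracle for end-to-end tests.
    """
    mpf = spec.mates_per_fragment
    refs: dict[str, RefTruth] = {}
    species_acc: dict[str, dict[str, float]] = {}
    for ref in spec.references:
        rc = ref.n_fragments * mpf
        uniq = (ref.n_fragments - ref.n_shared) * mpf
        if ref.n_shared and ref.decoy_score_offset > 0:
            uniq = ref.n_fragments * mpf  # decoy strictly worse: still unique
        nucl = rc * spec.read_length
        mism = _schedule_sum(ref.mismatches_per_read, rc)
        s_ab = s_abundance(rc, ref.length_bp, spec.paired)
        r_ab = 100.0 * rc / spec.total_clean_reads
        failed = set()
        if rc < min_read_count:
            failed.add("I")
        if not (mism / nucl) < max_mismatch_ratio:
            failed.add("II")
        if not s_ab > min_s_abundance:
            failed.add("III")
        if not (uniq / rc) > min_unique_fraction:
            failed.add("IV")
        sp = ref.lineage.name("species") or ref.name
        refs[ref.name] = RefTruth(
            ref.name, ref.db, sp, rc, uniq, nucl, mism, s_ab, r_ab, frozenset(failed)
        )
        acc = species_acc.setdefault(
            sp, {"rc": 0, "uniq": 0, "nucl": 0, "mism": 0, "s_ab": 0.0}
        )
        acc["rc"] += rc
        acc["uniq"] += uniq
        acc["nucl"] += nucl
        acc["mism"] += mism
        acc["s_ab"] += s_ab

    # species two-pass: all four criteria in the pre-cycle, then I, II and
    # the data-driven abundance floor T with IV dropped
    def sp_failed(acc: dict, use_iv: bool, s_floor: float) -> frozenset[str]:
        failed = set()
        if acc["rc"] < min_read_count:
            failed.add("I")
        if not (acc["mism"] / acc["nucl"]) < max_mismatch_ratio:
            failed.add("II")
        if acc["s_ab"] < s_floor if not use_iv else not acc["s_ab"] > s_floor:
            failed.add("III")
        if use_iv and not (acc["uniq"] / acc["rc"]) > min_unique_fraction:
            failed.add("IV")
        return frozenset(failed)

    pass1 = [
        sp for sp, acc in species_acc.items()
        if not sp_failed(acc, use_iv=True, s_floor=min_s_abundance)
    ]
    threshold = min((species_acc[sp]["s_ab"] for sp in pass1), default=min_s_abundance)
    accepted: set[str] = set()
    rejected: dict[str, frozenset[str]] = {}
    for sp, acc in species_acc.items():
        failed = sp_failed(acc, use_iv=False, s_floor=threshold)
        if failed:
            rejected[sp] = failed
        else:
            accepted.add(sp)
    return TruthTable(refs, frozenset(accepted), rejected)


# ---------------------------------------------------------------------------
# sequence and SAM emission

def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, read: np.ndarray, n_mismatches: int) -> np.ndarray:
    if n_mismatches == 0:
        return read
    read = read.copy()
    positions = rng.choice(len(read), size=n_mismatches, replace=False)
    for p in positions:
        choices = _BASES[_BASES != read[p]]
        read[p] = choices[rng.integers(0, len(choices))]
    return read


def _sam_line(
    qname: str, flag: int, rname: str, pos: int, cigar: str,
    rnext: str, pnext: int, tlen: int, seq: str, tags: str,
) -> str:
    return (
        f"{qname}\t{flag}\t{rname}\t{pos}\t60\t{cigar}\t{rnext}\t{pnext}\t{tlen}\t"
        f"{seq}\t{'I' * len(seq)}\t{tags}\n"
    )


def generate(spec: CommunitySpec, outdir: str | Path) -> FixtureBundle:
    """Materialize the fixture bundle; byte-stable for a fixed seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    L = spec.read_length
    k = spec.score_per_mismatch
    cigar = f"{L}M"

    # reference sequences (planted refs then decoys, in spec order)
    seqs: dict[str, np.ndarray] = {}
    ref_db: dict[str, str] = {}
    for ref in spec.references:
        seqs[ref.name] = _random_seq(rng, ref.length_bp)
        ref_db[ref.name] = ref.db
    for db, name, length in spec.decoy_refs:
        seqs[name] = _random_seq(rng, length)
        ref_db[name] = db

    fasta_path = outdir / "references.fasta"
    with open(fasta_path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            s = seq.tobytes().decode()
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")

    tax_path = outdir / "taxonomy.tsv"
    write_taxonomy_tsv([(r.name, r.lineage) for r in spec.references], tax_path)

    # one record buffer per database; headers list that database's references
    lines: dict[str, list[str]] = {d.name: [] for d in spec.databases}
    for ref in spec.references:
        ref_seq = seqs[ref.name]
        schedule = ref.mismatches_per_read
        rec_idx = 0
        for frag in range(ref.n_fragments):
            qname = f"{ref.name}:frag{frag}"
            shared = frag < ref.n_shared
            if spec.paired:
                start = int(rng.integers(0, ref.length_bp - spec.insert_size + 1))
                p1, p2 = start, start + spec.insert_size - L
                mates = [(p1, 99), (p2, 147)]
            else:
                start = int(rng.integers(0, ref.length_bp - L + 1))
                mates = [(start, 0)]
            scores = []
            for mate_i, (pos0, flag) in enumerate(mates):
                m = schedule[rec_idx % len(schedule)]
                rec_idx += 1
                read = _mutate(rng, ref_seq[pos0 : pos0 + L], m)
                score = L - k * m
                scores.append(score)
                if spec.paired:
                    other = mates[1 - mate_i][0]
                    tlen = spec.insert_size if mate_i == 0 else -spec.insert_size
                    line = _sam_line(
                        qname, flag, ref.name, pos0 + 1, cigar, "=", other + 1,
                        tlen, read.tobytes().decode(), f"NM:i:{m}\tAS:i:{score}",
                    )
                else:
                    line = _sam_line(
                        qname, flag, ref.name, pos0 + 1, cigar, "*", 0, 0,
                        read.tobytes().decode(), f"NM:i:{m}\tAS:i:{score}",
                    )
                lines[ref.db].append(line)
            if shared:
                decoy_db, decoy_ref = ref.decoy
                decoy_len = len(seqs[decoy_ref])
                span = spec.insert_size if spec.paired else L
                start = int(rng.integers(0, decoy_len - span + 1))
                for mate_i, score in enumerate(scores):
                    d_score = score - ref.decoy_score_offset
                    pos0 = start if mate_i == 0 else start + spec.insert_size - L
                    flag = [99, 147][mate_i] if spec.paired else 0
                    read = seqs[decoy_ref][pos0 : pos0 + L]
                    if spec.paired:
                        other = start + spec.insert_size - L if mate_i == 0 else start
                        tlen = spec.insert_size if mate_i == 0 else -spec.insert_size
                        line = _sam_line(
                            qname, flag, decoy_ref, pos0 + 1, cigar, "=", other + 1,
                            tlen, read.tobytes().decode(), f"NM:i:0\tAS:i:{d_score}",
                        )
                    else:
                        line = _sam_line(
                            qname, flag, decoy_ref, pos0 + 1, cigar, "*", 0, 0,
                            read.tobytes().decode(), f"NM:i:0\tAS:i:{d_score}",
                        )
                    lines[decoy_db].append(line)

    sam_paths: dict[str, Path] = {}
    for db in spec.databases:
        path = outdir / f"{db.name}.sam"
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for name in seqs:
                if ref_db[name] == db.name:
                    fh.write(f"@SQ\tSN:{name}\tLN:{len(seqs[name])}\n")
            fh.writelines(lines[db.name])
        sam_paths[db.name] = path

    context = SampleContext(spec.total_clean_reads, spec.paired)
    return FixtureBundle(fasta_path, tax_path, sam_paths, context, truth_from_spec(spec), spec)


# ---------------------------------------------------------------------------
# stock study designs

def default_community(seed: int = 0) -> CommunitySpec:
    """The planted-recovery benchmark: 8 species (two multi-strain) plus four
    low-abundance contaminants, each engineered to violate exactly one
    acceptance criterion (read count 9; mismatch ratio 0.015; size-normalized
    abundance 0.009; unique read fraction 0.004).

    Single-end 100 bp reads, so ReadCount equals the planted read numbers
    directly.  Genome sizes are scaled to the tens-of-kilobases range to keep
    the fixture fast while leaving every planted species' margin well clear of
    all four thresholds.
    """
    dbs = (
        DatabaseSpec("bacteria", "bestmode", 1),
        DatabaseSpec("decoys", "bestmode", 2),
    )
    lin = make_lineage

    def sp(i: int, name: str) -> tuple[int, str]:
        return (1000 + i, name)

    def gen(i: int, name: str) -> tuple[int, str]:
        return (2000 + i, name)

    g_bac = gen(1, "Bacillus")
    g_esc = gen(2, "Escherichia")
    g_pse = gen(3, "Pseudomonas")
    g_rho = gen(4, "Rhodobacter")
    g_str = gen(5, "Streptomyces")
    g_mic = gen(6, "Micrococcus")
    g_fra = gen(7, "Frankia")

    refs = (
        PlantedReference("Bamy_DSM7", "bacteria", 60000, 400,
                         lin("Bamy_DSM7", sp(1, "Bacillus amyloliquefaciens"), g_bac),
                         mismatches_per_read=(0, 1)),
        PlantedReference("Ecoli_K12", "bacteria", 80000, 500,
                         lin("Ecoli_K12", sp(2, "Escherichia coli"), g_esc),
                         mismatches_per_read=(0, 1)),
        PlantedReference("Pput_KT2440", "bacteria", 50000, 300,
                         lin("Pput_KT2440", sp(3, "Pseudomonas putida"), g_pse),
                         mismatches_per_read=(0, 1)),
        PlantedReference("Rcap_SB1003", "bacteria", 120000, 800,
                         lin("Rcap_SB1003", sp(4, "Rhodobacter capsulatus"), g_rho),
                         mismatches_per_read=(0, 1),
                         n_shared=100, decoy=("decoys", "decoy_rcap")),
        PlantedReference("Scoe_A32", "bacteria", 40000, 350,
                         lin("Scoe_A32", sp(5, "Streptomyces coelicolor"), g_str),
                         mismatches_per_read=(0, 1)),
        PlantedReference("Mlut_NCTC2665", "bacteria", 90000, 600,
                         lin("Mlut_NCTC2665", sp(6, "Micrococcus luteus"), g_mic),
                         mismatches_per_read=(0, 1)),
        # two multi-strain species
        PlantedReference("Paer_PAO1", "bacteria", 70000, 350,
                         lin("Paer_PAO1", sp(7, "Pseudomonas aeruginosa"), g_pse),
                         mismatches_per_read=(0, 1)),
        PlantedReference("Paer_PA14", "bacteria", 70000, 280,
                         lin("Paer_PA14", sp(7, "Pseudomonas aeruginosa"), g_pse),
                         mismatches_per_read=(0, 1)),
        PlantedReference("Fsp_CcI3", "bacteria", 50000, 250,
                         lin("Fsp_CcI3", sp(8, "Frankia sp."), g_fra),
                         mismatches_per_read=(0, 1)),
        PlantedReference("Fsp_EAN1", "bacteria", 60000, 330,
                         lin("Fsp_EAN1", sp(8, "Frankia sp."), g_fra),
                         mismatches_per_read=(0, 1)),
        # contaminants: each violates exactly one criterion at strain level
        PlantedReference("cont_readcount", "bacteria", 10000, 9,
                         lin("cont_readcount", sp(20, "Contaminans paucilectus"), gen(20, "Contaminans")),
                         violates="I"),
        PlantedReference("cont_mismatch", "bacteria", 10000, 20,
                         lin("cont_mismatch", sp(21, "Contaminans mutabilis"), gen(21, "Contaminans2")),
                         mismatches_per_read=(1, 2), violates="II"),
        PlantedReference("cont_abundance", "bacteria", 200000, 18,
                         lin("cont_abundance", sp(22, "Contaminans rarus"), gen(22, "Contaminans3")),
                         violates="III"),
        PlantedReference("cont_nonunique", "bacteria", 100000, 250,
                         lin("cont_nonunique", sp(23, "Contaminans ambiguus"), gen(23, "Contaminans4")),
                         n_shared=249, decoy=("decoys", "decoy_cont"), violates="IV"),
    )
    decoys = (
        ("decoys", "decoy_rcap", 120000),
        ("decoys", "decoy_cont", 100000),
    )
    return CommunitySpec(
        references=refs,
        databases=dbs,
        decoy_refs=decoys,
        read_length=100,
        paired=False,
        total_clean_reads=6000,
        seed=seed,
    )


def paired_community(seed: int = 0) -> CommunitySpec:
    """A small paired-end sample over a genome database (bestmode), a decoy
    database, and a gene database in fullmode that shares content with the
    genomes — the layout used to exercise pair filtering and dual bestmode /
    fullmode assignment."""
    dbs = (
        DatabaseSpec("genomes", "bestmode", 1),
        DatabaseSpec("decoys", "bestmode", 2),
        DatabaseSpec("genes", "fullmode", 3),
    )
    lin = make_lineage
    refs = (
        PlantedReference("gA", "genomes", 40000, 200,
                         lin("gA", (1101, "Alpha primus"), (2101, "Alphagenus")),
                         mismatches_per_read=(0, 1)),
        PlantedReference("gB", "genomes", 30000, 150,
                         lin("gB", (1102, "Beta secundus"), (2102, "Betagenus")),
                         mismatches_per_read=(0, 0, 1)),
        PlantedReference("gC", "genomes", 25000, 120,
                         lin("gC", (1103, "Gamma tertius"), (2103, "Gammagenus")),
                         n_shared=30, decoy=("decoys", "decoy_gC")),
        PlantedReference("resgene1", "genes", 2000, 40,
                         lin("resgene1", (1104, "Resistance gene 1"), (2104, "Genecluster"))),
    )
    decoys = (("decoys", "decoy_gC", 25000),)
    return CommunitySpec(
        references=refs,
        databases=dbs,
        decoy_refs=decoys,
        read_length=100,
        insert_size=300,
        paired=True,
        total_clean_reads=2000,
        seed=seed,
    )
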