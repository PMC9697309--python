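"""Pedigree-structured codon-sequence simulator with known per-branch dN/dS.

Generates every input the pipeline consumes -- per-locus codon alignments,
per-sample transcript FASTAs, a ProteinOrtho-style ortholog table, an
annotation table, diploid genotypes with read pileups, and a miniature GO
ontology -- together with a truth table for testing.

The pedigree mirrors the five-sample study design: one individual of
parental species A, two individuals of parental species B (carrying
intraspecific polymorphism), and two F2 hybrids.  Per locus, an ancestral
stop-free codon sequence evolves along the two-species split; each hybrid
is a Mendelian mosaic of parental alleles (one recombination breakpoint per
locus, drawn uniformly on codon boundaries) followed by a short private
branch evolved under a configurable dN/dS.

Selection intensity is enforced by acceptance-rejection on proposed
single-base changes: nonsynonymous proposals are accepted with probability
``min(1, omega)`` and synonymous ones with ``min(1, 1/omega)``, so the
realized nonsynonymous:synonymous substitution mix matches the target ratio
relative to neutrality.  Proposals creating stop codons are rejected
outright; all emitted sequences translate without internal stops.  This is
a calibration device for counting estimators, not a substitute for
rate-matrix codon-model simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment_prep import CodonAlignment
from .dnds import GENETIC_CODE, STOP_CODONS
from .ortholog_curation import AnnotationRecord
from .sample_design import SampleDesign, SampleRole

_BASES = "ACGT"
_SENSE_CODONS = tuple(sorted(GENETIC_CODE))

#: The five-sample study design the defaults emulate.
DEFAULT_DESIGN = SampleDesign(
    [
        ("parentA_1", SampleRole.PARENT_A),
        ("parentB_1", SampleRole.PARENT_B),
        ("parentB_2", SampleRole.PARENT_B),
        ("hybrid_1", SampleRole.HYBRID),
        ("hybrid_2", SampleRole.HYBRID),
    ]
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Rates are substitutions per nucleotide site.  ``injected_loci`` lists
    ``(locus_index, hybrid_branch_omega)`` pairs whose hybrid branches
    evolve under the given dN/dS instead of ``background_omega``.
    """

    seed: int = 0
    n_loci: int = 200
    codons_per_locus: int = 300
    species_divergence_sub_per_site: float = 0.05
    background_omega: float = 0.2
    injected_loci: tuple[tuple[int, float], ...] = ()
    het_site_density: float = 0.02
    pileup_depth: int = 50
    pileup_error_rate: float = 0.001
    intraspecific_divergence_sub_per_site: float = 0.005
    hybrid_branch_sub_per_site: float = 0.10
    fraction_unannotated: float = 0.10
    fraction_reproduction: float = 0.10
    include_decoy_groups: bool = True

    def __post_init__(self) -> None:
        if self.codons_per_locus < 30:
            raise ValueError("codons_per_locus must be >= 30")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        for name in (
            "species_divergence_sub_per_site",
            "background_omega",
            "het_site_density",
            "pileup_error_rate",
            "intraspecific_divergence_sub_per_site",
            "hybrid_branch_sub_per_site",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.background_omega <= 0:
            raise ValueError("background_omega must be > 0")
        for idx, w in self.injected_loci:
            if not 0 <= idx < self.n_loci:
                raise ValueError(f"injected locus index {idx} out of range")
            if w <= 0:
                raise ValueError(f"injected omega must be > 0, got {w}")
        if self.pileup_depth < 0:
            raise ValueError("pileup_depth must be >= 0")


@dataclass
class DiploidGenotype:
    """Two haplotypes per sample and locus; hap1 is the emitted sequence."""

    locus_id: str
    sample_id: str
    hap1: str
    hap2: str
    het_positions: tuple[int, ...]


@dataclass
class SimulationResult:
    design: SampleDesign
    config: SimulationConfig
    alignments: list[CodonAlignment]
    ortholog_rows: list[dict[str, list[str]]]
    annotations: list[AnnotationRecord]
    genotypes: list[DiploidGenotype]
    truth: pd.DataFrame

    def contig_sequences(self) -> dict[str, str]:
        """contig_id -> ungapped sequence over all samples and loci."""
        seqs: dict[str, str] = {}
        for aln in self.alignments:
            for sample, seq in aln.sequences.items():
                seqs[contig_name(aln.locus_id, sample)] = seq
        return seqs


def contig_name(locus_id: str, sample_id: str) -> str:
    return f"{locus_id}__{sample_id}"


def random_codon_sequence(n_codons: int, rng: np.random.Generator) -> str:
    """Ancestral sequence: codons drawn uniformly from the 61 sense codons."""
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def evolve_sequence(
    seq: str, n_substitutions: int, omega: float, rng: np.random.Generator
) -> str:
    """Apply ``n_substitutions`` accepted single-base changes under ``omega``.

    Proposals are uniform over positions and alternative bases; stop-codon
    proposals are rejected and not counted.  Acceptance probability is
    ``min(1, omega)`` for nonsynonymous and ``min(1, 1/omega)`` for
    synonymous proposals.
    """
    chars = list(seq)
    n_sites = len(chars)
    p_nonsyn = min(1.0, omega)
    p_syn = min(1.0, 1.0 / omega)
    accepted = 0
    while accepted < n_substitutions:
        pos = int(rng.integers(0, n_sites))
        old = chars[pos]
        new = _BASES[int(rng.integers(0, 3))]
        if new >= old:  # map 0..2 onto the three non-identical bases
            new = _BASES[(_BASES.index(new) + 1) % 4]
            if new == old:
                continue
        c0 = pos - pos % 3
        codon = "".join(chars[c0 : c0 + 3])
        mutated = codon[: pos - c0] + new + codon[pos - c0 + 1 :]
        if mutated in STOP_CODONS:
            continue
        synonymous = GENETIC_CODE[codon] == GENETIC_CODE[mutated]
        p_accept = p_syn if synonymous else p_nonsyn
        if p_accept < 1.0 and rng.random() >= p_accept:
            continue
        chars[pos] = new
        accepted += 1
    return "".join(chars)


def _branch_subs(rate: float, n_sites: int, rng: np.random.Generator) -> int:
    return int(rng.poisson(rate * n_sites))


def _mosaic(
    seq_a: str,
    seqs_b: Sequence[str],
    n_codons: int,
    rng: np.random.Generator,
) -> str:
    """F2 hybrid haplotype: parental allele per segment, one breakpoint."""
    breakpoint_codon = int(rng.integers(1, n_codons)) * 3
    segments = []
    for bounds in ((0, breakpoint_codon), (breakpoint_codon, 3 * n_codons)):
        if rng.random() < 0.5:
            allele = seq_a
        else:
            allele = seqs_b[int(rng.integers(0, len(seqs_b)))]
        segments.append(allele[bounds[0] : bounds[1]])
    return "".join(segments)


def _second_allele(
    seq: str, density: float, rng: np.random.Generator
) -> tuple[str, tuple[int, ...]]:
    """Companion haplotype with heterozygous sites at the given density.

    Alternative bases that would create a stop codon are re-drawn so both
    haplotypes stay translatable.
    """
    chars = list(seq)
    het: list[int] = []
    n_het = int(rng.binomial(len(chars), density)) if density > 0 else 0
    positions = rng.choice(len(chars), size=n_het, replace=False) if n_het else []
    for pos in sorted(int(p) for p in positions):
        old = chars[pos]
        alternatives = [b for b in _BASES if b != old]
        rng.shuffle(alternatives)
        for new in alternatives:
            c0 = pos - pos % 3
            codon = "".join(chars[c0 : c0 + 3])
            mutated = codon[: pos - c0] + new + codon[pos - c0 + 1 :]
            if mutated not in STOP_CODONS:
                chars[pos] = new
                het.append(pos)
                break
    return "".join(chars), tuple(het)


def simulate_design(
    config: SimulationConfig, design: SampleDesign = DEFAULT_DESIGN
) -> SimulationResult:
    """Simulate the full multi-sample dataset for the given conditions.

    Deterministic given ``config.seed``; the same configuration always
    yields byte-identical outputs.
    """
    samples_a = design.samples_with_role(SampleRole.PARENT_A)
    samples_b = design.samples_with_role(SampleRole.PARENT_B)
    hybrids = design.samples_with_role(SampleRole.HYBRID)
    rng = np.random.default_rng([config.seed, 101])
    injected = dict(config.injected_loci)
    n_sites = 3 * config.codons_per_locus
    half_split = config.species_divergence_sub_per_site / 2.0
    half_intra = config.intraspecific_divergence_sub_per_site / 2.0

    alignments: list[CodonAlignment] = []
    genotypes: list[DiploidGenotype] = []
    truth_rows: list[dict[str, object]] = []

    fixture = emit_go_fixture()
    ann_rng = np.random.default_rng([config.seed, 202])
    n_unann = int(round(config.fraction_unannotated * config.n_loci))
    n_repro = int(round(config.fraction_reproduction * config.n_loci))
    order = ann_rng.permutation(config.n_loci)
    unannotated = set(int(i) for i in order[:n_unann])
    repro_loci = set(int(i) for i in order[n_unann : n_unann + n_repro])

    annotations: list[AnnotationRecord] = []

    for i in range(config.n_loci):
        locus_id = f"locus_{i:05d}"
        ancestor = random_codon_sequence(config.codons_per_locus, rng)
        seq_a = evolve_sequence(
            ancestor, _branch_subs(half_split, n_sites, rng),
            config.background_omega, rng,
        )
        seq_b_root = evolve_sequence(
            ancestor, _branch_subs(half_split, n_sites, rng),
            config.background_omega, rng,
        )
        b_seqs = [
            evolve_sequence(
                seq_b_root, _branch_subs(half_intra, n_sites, rng),
                config.background_omega, rng,
            )
            for _ in samples_b
        ]
        hybrid_omega = injected.get(i, config.background_omega)
        sequences: dict[str, str] = {}
        for s in samples_a:
            sequences[s] = seq_a
        for s, seq in zip(samples_b, b_seqs):
            sequences[s] = seq
        for s in hybrids:
            mosaic = _mosaic(seq_a, b_seqs, config.codons_per_locus, rng)
            sequences[s] = evolve_sequence(
                mosaic,
                _branch_subs(config.hybrid_branch_sub_per_site, n_sites, rng),
                hybrid_omega,
                rng,
            )
        alignments.append(CodonAlignment(locus_id, sequences))

        row: dict[str, object] = {
            "locus_id": locus_id,
            "injected": i in injected,
            "hybrid_branch_omega": hybrid_omega,
            "background_omega": config.background_omega,
            "annotated": i not in unannotated,
            "reproduction": i in repro_loci,
        }
        for sample, seq in sequences.items():
            hap2, het_pos = _second_allele(seq, config.het_site_density, rng)
            genotypes.append(
                DiploidGenotype(locus_id, sample, seq, hap2, het_pos)
            )
            row[f"n_het_{sample}"] = len(het_pos)
            row[f"het_positions_{sample}"] = ",".join(map(str, het_pos))
        truth_rows.append(row)

        if i not in unannotated:
            if i in repro_loci:
                k = int(ann_rng.integers(1, 4))
                picked = ann_rng.choice(
                    fixture.reproduction_leaves, size=k, replace=False
                )
                terms = tuple(sorted(str(t) for t in picked))
            else:
                terms = (
                    (str(ann_rng.choice(fixture.decoy_terms)),)
                    if ann_rng.random() < 0.5
                    else ()
                )
            annotations.append(
                AnnotationRecord(
                    contig_id=contig_name(locus_id, design.sample_ids[0]),
                    reference_gene=f"GENE_{i:05d}",
                    lineage_label="Spermatophyta",
                    mapped_fragments=((0, n_sites),),
                    go_terms=terms,
                )
            )

    ortholog_rows = [
        {s: [contig_name(aln.locus_id, s)] for s in design.sample_ids}
        for aln in alignments
    ]
    if config.include_decoy_groups:
        ortholog_rows.extend(_decoy_rows(design, annotations))

    truth = pd.DataFrame(truth_rows)
    return SimulationResult(
        design=design,
        config=config,
        alignments=alignments,
        ortholog_rows=ortholog_rows,
        annotations=annotations,
        genotypes=genotypes,
        truth=truth,
    )


def _decoy_rows(
    design: SampleDesign, annotations: list[AnnotationRecord]
) -> list[dict[str, list[str]]]:
    """Ortholog-table rows exercising each curation filter.

    One multi-copy group, one group missing a sample, one single-copy group
    with short ORFs, and one single-copy contaminant (fungal lineage).
    """
    ids = design.sample_ids
    multi = {s: [f"decoy_multi__{s}"] for s in ids}
    multi[ids[0]] = [f"decoy_multi__{ids[0]}", f"decoy_multi__{ids[0]}b"]
    missing = {s: [f"decoy_missing__{s}"] for s in ids[1:]}
    missing[ids[0]] = []
    short = {s: [f"decoy_short__{s}"] for s in ids}
    contaminant = {s: [f"decoy_fungus__{s}"] for s in ids}
    annotations.append(
        AnnotationRecord(
            contig_id=f"decoy_fungus__{ids[0]}",
            reference_gene="GENE_FUNGUS",
            lineage_label="Fungi",
            mapped_fragments=((0, 120),),
        )
    )
    return [multi, missing, short, contaminant]


def decoy_sequences(design: SampleDesign, rng: np.random.Generator) -> dict[str, str]:
    """Sequences for the decoy contigs (short ORFs get 90 nt, others 600)."""
    seqs: dict[str, str] = {}
    for s in design.sample_ids:
        seqs[f"decoy_multi__{s}"] = random_codon_sequence(200, rng)
        seqs[f"decoy_multi__{s}b"] = random_codon_sequence(200, rng)
        seqs[f"decoy_missing__{s}"] = random_codon_sequence(200, rng)
        seqs[f"decoy_short__{s}"] = random_codon_sequence(30, rng)
        seqs[f"decoy_fungus__{s}"] = random_codon_sequence(200, rng)
    return seqs


def simulate_pileups(
    genotypes: Iterable[DiploidGenotype], config: SimulationConfig
) -> dict[str, str]:
    """mpileup text per sample from diploid genotypes.

    Per position, ``pileup_depth`` reads draw their source haplotype
    uniformly; each read base is replaced by a uniform different base with
    probability ``pileup_error_rate``.  The reference column is haplotype 1,
    so matching reads are emitted as ``.``.
    """
    rng = np.random.default_rng([config.seed, 303])
    per_sample: dict[str, list[str]] = {}
    depth = config.pileup_depth
    for g in genotypes:
        lines = per_sample.setdefault(g.sample_id, [])
        for pos, (ref, alt) in enumerate(zip(g.hap1, g.hap2)):
            from_hap2 = int(rng.binomial(depth, 0.5)) if ref != alt else 0
            bases = [alt] * from_hap2 + [ref] * (depth - from_hap2)
            if config.pileup_error_rate > 0:
                n_err = int(rng.binomial(depth, config.pileup_error_rate))
                for j in rng.choice(depth, size=n_err, replace=False) if n_err else []:
                    j = int(j)
                    others = [b for b in _BASES if b != bases[j]]
                    bases[j] = others[int(rng.integers(0, 3))]
            rng.shuffle(bases)
            column = "".join("." if b == ref else b for b in bases)
            lines.append(
                f"{g.locus_id}\t{pos + 1}\t{ref}\t{depth}\t{column}\t{'I' * depth}"
            )
    return {sample: "\n".join(lines) + "\n" for sample, lines in per_sample.items()}


# ---------------------------------------------------------------------------
# miniature GO ontology fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GoFixture:
    obo_text: str
    reproduction_roots: tuple[str, ...]
    reproduction_leaves: tuple[str, ...]
    table_terms: tuple[str, ...]
    decoy_terms: tuple[str, ...]


# (id, name, namespace, is_a parents); a synthetic miniature whose topology
# only loosely follows the real ontology -- sufficient for exercising
# ancestor traversal and subtree membership, not for real annotation.
_FIXTURE_TERMS: tuple[tuple[str, str, str, tuple[str, ...]], ...] = (
    ("GO:0008150", "biological_process", "biological_process", ()),
    ("GO:0003674", "molecular_function", "molecular_function", ()),
    ("GO:0005575", "cellular_component", "cellular_component", ()),
    # reproduction roots
    ("GO:0000003", "reproduction", "biological_process", ("GO:0008150",)),
    ("GO:0022414", "reproductive process", "biological_process", ("GO:0008150",)),
    ("GO:0048229", "gametophyte development", "biological_process", ("GO:0022414",)),
    ("GO:1903046", "meiotic cell cycle process", "biological_process", ("GO:0022414",)),
    ("GO:0048236", "plant-type sporogenesis", "biological_process", ("GO:0022414",)),
    ("GO:0000741", "karyogamy", "biological_process", ("GO:0022414",)),
    # intermediates
    ("GO:0003006", "developmental process involved in reproduction", "biological_process", ("GO:0022414",)),
    ("GO:0032504", "multicellular organism reproduction", "biological_process", ("GO:0000003",)),
    ("GO:0009566", "fertilization", "biological_process", ("GO:0032504",)),
    ("GO:0140013", "meiotic nuclear division", "biological_process", ("GO:1903046",)),
    ("GO:0007127", "meiosis I", "biological_process", ("GO:1903046",)),
    ("GO:0009875", "pollen-pistil interaction", "biological_process", ("GO:0022414",)),
    ("GO:0009790", "embryo development", "biological_process", ("GO:0003006",)),
    ("GO:0000742", "karyogamy involved in conjugation with cellular fusion", "biological_process", ("GO:0000741",)),
    ("GO:0000743", "nuclear migration involved in conjugation with cellular fusion", "biological_process", ("GO:0000742",)),
    # leaves used by annotation tables (female/meiosis/embryo side)
    ("GO:0009908", "flower development", "biological_process", ("GO:0003006",)),
    ("GO:0048481", "plant ovule development", "biological_process", ("GO:0003006",)),
    ("GO:0007143", "female meiotic nuclear division", "biological_process", ("GO:0140013",)),
    ("GO:0007140", "male meiotic nuclear division", "biological_process", ("GO:0140013",)),
    ("GO:0007129", "homologous chromosome pairing at meiosis", "biological_process", ("GO:0007127",)),
    ("GO:0007091", "metaphase/anaphase transition of mitotic cell cycle", "biological_process", ("GO:1903046",)),
    ("GO:0009554", "megasporogenesis", "biological_process", ("GO:0048236",)),
    ("GO:0009553", "embryo sac development", "biological_process", ("GO:0048229",)),
    ("GO:0009793", "embryo development ending in seed dormancy", "biological_process", ("GO:0009790",)),
    ("GO:0048316", "seed development", "biological_process", ("GO:0003006",)),
    # leaves, male side
    ("GO:0009556", "microsporogenesis", "biological_process", ("GO:0048236",)),
    ("GO:0009555", "pollen development", "biological_process", ("GO:0048229",)),
    ("GO:0048235", "pollen sperm cell differentiation", "biological_process", ("GO:0009555",)),
    ("GO:0010480", "microsporocyte differentiation", "biological_process", ("GO:0009556",)),
    ("GO:0048658", "anther wall tapetum development", "biological_process", ("GO:0003006",)),
    ("GO:0060321", "acceptance of pollen", "biological_process", ("GO:0009875",)),
    ("GO:0009846", "pollen germination", "biological_process", ("GO:0009875",)),
    ("GO:0009860", "pollen tube growth", "biological_process", ("GO:0009875",)),
    # metabolic decoys: no path into any reproduction root
    ("GO:0008152", "metabolic process", "biological_process", ("GO:0008150",)),
    ("GO:0006096", "glycolytic process", "biological_process", ("GO:0008152",)),
    ("GO:0005975", "carbohydrate metabolic process", "biological_process", ("GO:0008152",)),
    ("GO:0006412", "translation", "biological_process", ("GO:0008152",)),
    ("GO:0003824", "catalytic activity", "molecular_function", ("GO:0003674",)),
)

#: GO ids printed in the study's reproduction-annotation table.
TABLE_TERMS = (
    "GO:0009793", "GO:0007143", "GO:0007140", "GO:0009555", "GO:0009553",
    "GO:0007091", "GO:0048481", "GO:0048316", "GO:0009908", "GO:0048658",
    "GO:0009554", "GO:0009556", "GO:0007129", "GO:0060321", "GO:0009846",
    "GO:0009860",
)

_DECOY_TERMS = ("GO:0006096", "GO:0005975", "GO:0006412", "GO:0003824")


def emit_go_fixture() -> GoFixture:
    """A <=50-term ontology containing the six reproduction roots.

    Every root has a multi-level descendant chain, every annotation-table
    GO id appears exactly once, and decoy metabolic terms have no path into
    any reproduction root.  Includes one ``alt_id`` alias and one obsolete
    term to exercise parser tolerance.
    """
    lines = ["format-version: 1.2", "ontology: go-mini-synthetic", ""]
    for term_id, name, namespace, parents in _FIXTURE_TERMS:
        lines.append("[Term]")
        lines.append(f"id: {term_id}")
        lines.append(f"name: {name}")
        lines.append(f"namespace: {namespace}")
        if term_id == "GO:0007143":
            lines.append("alt_id: GO:0007144")
        for parent in parents:
            lines.append(f"is_a: {parent}")
        lines.append("")
    lines += [
        "[Term]",
        "id: GO:0099999",
        "name: obsolete synthetic placeholder",
        "namespace: biological_process",
        "is_obsolete: true",
        "",
    ]
    return GoFixture(
        obo_text="\n".join(lines),
        reproduction_roots=(
            "GO:0048229", "GO:0000003", "GO:0022414",
            "GO:1903046", "GO:0048236", "GO:0000741",
        ),
        reproduction_leaves=TABLE_TERMS,
        table_terms=TABLE_TERMS,
        decoy_terms=_DECOY_TERMS,
    )


# ---------------------------------------------------------------------------
# file writers (the exact dialects the pipeline reads)
# ---------------------------------------------------------------------------

def write_proteinortho_tsv(
    rows: Sequence[Mapping[str, Sequence[str]]],
    sample_ids: Sequence[str],
    path: str | Path,
) -> None:
    with Path(path).open("w") as fh:
        fh.write("# Species\tGenes\tAlg.-Conn.\t" + "\t".join(sample_ids) + "\n")
        for row in rows:
            cells = []
            n_species = sum(1 for s in sample_ids if row.get(s))
            n_genes = sum(len(row.get(s, [])) for s in sample_ids)
            for s in sample_ids:
                contigs = row.get(s, [])
                cells.append(",".join(contigs) if contigs else "*")
            fh.write(f"{n_species}\t{n_genes}\t1\t" + "\t".join(cells) + "\n")


def write_sample_fastas(
    result: SimulationResult, outdir: str | Path
) -> dict[str, Path]:
    """One transcript FASTA per sample (locus sequences + decoy contigs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seqs = result.contig_sequences()
    if result.config.include_decoy_groups:
        seqs.update(
            decoy_sequences(
                result.design, np.random.default_rng([result.config.seed, 404])
            )
        )
    paths: dict[str, Path] = {}
    for sample in result.design.sample_ids:
        path = outdir / f"{sample}.fasta"
        with path.open("w") as fh:
            for contig, seq in sorted(seqs.items()):
                if contig.endswith(f"__{sample}") or contig.endswith(f"__{sample}b"):
                    fh.write(f">{contig}\n{seq}\n")
        paths[sample] = path
    return paths


def write_dataset(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write the complete simulated dataset to ``outdir``.

    Layout: ``samples/<id>.fasta``, ``alignments/<locus>.fasta``,
    ``proteinortho.tsv``, ``annotations.tsv``, ``pileups/<id>.pileup``,
    ``go_mini.obo``, ``truth.tsv``.
    """
    from .ortholog_curation import write_annotation_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for aln in result.alignments:
        aln.write_fasta(aln_dir / f"{aln.locus_id}.fasta")
    paths["alignments"] = aln_dir

    write_sample_fastas(result, outdir / "samples")
    paths["samples"] = outdir / "samples"

    paths["proteinortho"] = outdir / "proteinortho.tsv"
    write_proteinortho_tsv(
        result.ortholog_rows, result.design.sample_ids, paths["proteinortho"]
    )

    paths["annotations"] = outdir / "annotations.tsv"
    write_annotation_tsv(result.annotations, paths["annotations"])

    pileup_dir = outdir / "pileups"
    pileup_dir.mkdir(exist_ok=True)
    for sample, text in simulate_pileups(result.genotypes, result.config).items():
        (pileup_dir / f"{sample}.pileup").write_text(text)
    paths["pileups"] = pileup_dir

    paths["obo"] = outdir / "go_mini.obo"
    paths["obo"].write_text(emit_go_fixture().obo_text)

    paths["truth"] = outdir / "truth.tsv"
    result.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
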