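"""Single-copy ortholog curation.

Reduces a multi-sample ortholog table (ProteinOrtho v6 TSV dialect) to loci
that are (1) single-copy in every sample of the design, (2) long enough
(ORF >= 300 nt by default), and (3) clean by annotation: not a
non-spermatophyte contaminant, not a putative paralog (same reference gene
hit by more than one contig), and not a chimera (a contig whose matches to
different reference genes overlap on the transcript).  Unannotated loci are
retained but flagged, because the final cascade reports them separately.

Each filter is idempotent and logs one discard reason per removed locus, so
``retained + discarded == input`` at every step.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .sample_design import SampleDesign

logger = logging.getLogger(__name__)

DEFAULT_SPERMATOPHYTE_LABELS = frozenset({"Spermatophyta"})


@dataclass(frozen=True)
class CurationParams:
    min_orf_nt: int = 300
    spermatophyte_labels: frozenset[str] = DEFAULT_SPERMATOPHYTE_LABELS

    def __post_init__(self) -> None:
        if self.min_orf_nt < 3 or self.min_orf_nt % 3 != 0:
            raise ValueError("min_orf_nt must be >= 3 and divisible by 3")


@dataclass(frozen=True)
class AnnotationRecord:
    """One contig-to-reference-gene match from the annotation table.

    ``mapped_fragments`` are half-open 0-based intervals on the transcript
    where the reference protein maps; a contig matching several reference
    genes has one record per gene.
    """

    contig_id: str
    reference_gene: str = ""
    lineage_label: str = ""
    mapped_fragments: tuple[tuple[int, int], ...] = ()
    go_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for start, end in self.mapped_fragments:
            if not start < end:
                raise ValueError(
                    f"contig {self.contig_id}: invalid interval [{start}, {end})"
                )


@dataclass
class LocusRecord:
    """A candidate single-copy locus: exactly one contig per sample."""

    locus_id: str
    contigs: dict[str, str]  # sample_id -> contig_id
    annotated: bool = False
    reference_genes: tuple[str, ...] = ()
    go_terms: tuple[str, ...] = ()


@dataclass
class OrthologTable:
    """Rows of ortholog groups mapping sample_id -> contig id list."""

    rows: list[dict[str, list[str]]]

    @classmethod
    def read_proteinortho(cls, path: str | Path) -> "OrthologTable":
        """Parse a ProteinOrtho v6 TSV.

        Header ``# Species\tGenes\tAlg.-Conn.`` then one column per sample;
        ``*`` marks absence and ``,`` separates co-orthologs.
        """
        path = Path(path)
        rows: list[dict[str, list[str]]] = []
        with path.open() as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            if header is None:
                logger.warning("empty ortholog table %s", path)
                return cls(rows=[])
            if len(header) < 4:
                raise ValueError(
                    f"{path}: expected ProteinOrtho header with >=4 columns"
                )
            samples = header[3:]
            for line in reader:
                row: dict[str, list[str]] = {}
                for sample, cell in zip(samples, line[3:]):
                    row[sample] = [] if cell in ("*", "") else cell.split(",")
                rows.append(row)
        return cls(rows=rows)

    def validate_against(self, design: SampleDesign) -> None:
        for i, row in enumerate(self.rows):
            missing = set(design.sample_ids) - set(row)
            if missing:
                raise ValueError(
                    f"ortholog table row {i} lacks columns for samples "
                    f"{sorted(missing)}"
                )


@dataclass
class DiscardEntry:
    locus_id: str
    stage: str
    reason: str


def select_single_copy(
    table: OrthologTable, design: SampleDesign
) -> tuple[list[LocusRecord], list[DiscardEntry]]:
    """Keep only groups with exactly one contig in every design sample."""
    if not table.rows:
        logger.warning("empty ortholog table: no loci to curate")
        return [], []
    table.validate_against(design)
    contig_seen: dict[str, str] = {}
    retained: list[LocusRecord] = []
    discards: list[DiscardEntry] = []
    for i, row in enumerate(table.rows):
        locus_id = f"locus_{i:05d}"
        bad = [
            s for s in design.sample_ids if len(row.get(s, [])) != 1
        ]
        if bad:
            detail = ", ".join(
                f"{s}:{len(row.get(s, []))} contigs" for s in bad
            )
            discards.append(
                DiscardEntry(locus_id, "single_copy", f"not single-copy ({detail})")
            )
            continue
        contigs = {s: row[s][0] for s in design.sample_ids}
        for cid in contigs.values():
            if cid in contig_seen:
                raise ValueError(
                    f"duplicate contig id {cid!r} in groups "
                    f"{contig_seen[cid]} and {locus_id}"
                )
            contig_seen[cid] = locus_id
        retained.append(LocusRecord(locus_id=locus_id, contigs=contigs))
    return retained, discards


def orf_length_filter(
    loci: Sequence[LocusRecord],
    sequences: Mapping[str, str],
    params: CurationParams = CurationParams(),
) -> tuple[list[LocusRecord], list[DiscardEntry]]:
    """Drop loci where any sample's ORF is shorter than ``min_orf_nt``.

    The boundary is strict: an ORF of exactly ``min_orf_nt`` is retained.
    A contig without a sequence is a hard error.
    """
    retained: list[LocusRecord] = []
    discards: list[DiscardEntry] = []
    for locus in loci:
        short = []
        for sample, contig in locus.contigs.items():
            if contig not in sequences:
                raise KeyError(
                    f"no ORF sequence for contig {contig!r} "
                    f"(locus {locus.locus_id}, sample {sample})"
                )
            if len(sequences[contig]) < params.min_orf_nt:
                short.append(f"{contig}:{len(sequences[contig])}nt")
        if short:
            discards.append(
                DiscardEntry(
                    locus.locus_id,
                    "orf_length",
                    f"ORF < {params.min_orf_nt} nt ({', '.join(short)})",
                )
            )
        else:
            retained.append(locus)
    return retained, discards


def _fragments_overlap(frags: Iterable[tuple[int, int]]) -> bool:
    ordered = sorted(frags)
    return any(
        ordered[i][1] > ordered[i + 1][0] for i in range(len(ordered) - 1)
    )


def annotation_clean(
    loci: Sequence[LocusRecord],
    annotations: Iterable[AnnotationRecord],
    params: CurationParams = CurationParams(),
) -> tuple[list[LocusRecord], list[DiscardEntry]]:
    """Annotation-based contaminant/paralog/chimera removal.

    Rules, applied in order on the surviving set:

    1. any contig of the locus carries a lineage label outside
       ``spermatophyte_labels`` -> removed as putative contaminant;
    2. a reference gene claimed by more than one distinct contig -> all loci
       holding those contigs removed as putative paralogs;
    3. a contig matching multiple reference genes whose mapped fragments
       overlap on the transcript -> removed; non-overlapping multi-gene
       matches are retained.

    Loci with no annotation at all pass through with ``annotated=False``.
    """
    by_contig: dict[str, list[AnnotationRecord]] = {}
    for rec in annotations:
        by_contig.setdefault(rec.contig_id, []).append(rec)

    discards: list[DiscardEntry] = []

    # rule 1: contaminants
    surviving: list[LocusRecord] = []
    for locus in loci:
        bad_lineages = {
            rec.lineage_label
            for cid in locus.contigs.values()
            for rec in by_contig.get(cid, [])
            if rec.lineage_label and rec.lineage_label not in params.spermatophyte_labels
        }
        if bad_lineages:
            discards.append(
                DiscardEntry(
                    locus.locus_id,
                    "contaminant",
                    f"non-spermatophyte lineage ({', '.join(sorted(bad_lineages))})",
                )
            )
        else:
            surviving.append(locus)

    # rule 2: paralogs -- same reference gene on >1 distinct contig
    gene_claims: dict[str, set[str]] = {}
    for locus in surviving:
        for cid in locus.contigs.values():
            for rec in by_contig.get(cid, []):
                if rec.reference_gene:
                    gene_claims.setdefault(rec.reference_gene, set()).add(cid)
    paralog_contigs = {
        cid for contigs in gene_claims.values() if len(contigs) > 1 for cid in contigs
    }
    after_paralogs: list[LocusRecord] = []
    for locus in surviving:
        hit = sorted(set(locus.contigs.values()) & paralog_contigs)
        if hit:
            genes = sorted(
                {
                    rec.reference_gene
                    for cid in hit
                    for rec in by_contig.get(cid, [])
                    if rec.reference_gene and len(gene_claims[rec.reference_gene]) > 1
                }
            )
            discards.append(
                DiscardEntry(
                    locus.locus_id,
                    "paralog",
                    f"reference gene(s) {', '.join(genes)} matched by multiple contigs",
                )
            )
        else:
            after_paralogs.append(locus)

    # rule 3: overlapping multi-gene matches on one contig
    retained: list[LocusRecord] = []
    for locus in after_paralogs:
        chimeric = False
        for cid in locus.contigs.values():
            recs = [r for r in by_contig.get(cid, []) if r.reference_gene]
            if len(recs) > 1:
                all_frags = [f for r in recs for f in r.mapped_fragments]
                if _fragments_overlap(all_frags):
                    discards.append(
                        DiscardEntry(
                            locus.locus_id,
                            "fragment_overlap",
                            f"contig {cid} matches multiple reference genes "
                            "with overlapping mapped fragments",
                        )
                    )
                    chimeric = True
                    break
        if chimeric:
            continue
        recs = [
            r
            for cid in locus.contigs.values()
            for r in by_contig.get(cid, [])
        ]
        genes = tuple(sorted({r.reference_gene for r in recs if r.reference_gene}))
        gos = tuple(sorted({g for r in recs for g in r.go_terms}))
        retained.append(
            LocusRecord(
                locus_id=locus.locus_id,
                contigs=locus.contigs,
                annotated=bool(genes),
                reference_genes=genes,
                go_terms=gos,
            )
        )
    return retained, discards


def read_annotation_tsv(path: str | Path) -> list[AnnotationRecord]:
    """Read the annotation table.

    Columns: contig_id, reference_gene, lineage, fragments
    (``start-end`` semicolon-separated, half-open 0-based), go_terms
    (``GO:NNNNNNN`` separated by ``,`` or ``^``).
    """
    records: list[AnnotationRecord] = []
    with Path(path).open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            frag_field = (row.get("fragments") or "").strip()
            frags = tuple(
                tuple(int(x) for x in part.split("-"))
                for part in frag_field.split(";")
                if part
            )
            go_field = (row.get("go_terms") or "").replace("^", ",")
            gos = tuple(t.strip() for t in go_field.split(",") if t.strip())
            records.append(
                AnnotationRecord(
                    contig_id=row["contig_id"],
                    reference_gene=(row.get("reference_gene") or "").strip(),
                    lineage_label=(row.get("lineage") or "").strip(),
                    mapped_fragments=frags,  # type: ignore[arg-type]
                    go_terms=gos,
                )
            )
    return records


def write_annotation_tsv(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["contig_id", "reference_gene", "lineage", "fragments", "go_terms"])
        for rec in records:
            writer.writerow(
                [
                    rec.contig_id,
                    rec.reference_gene,
                    rec.lineage_label,
                    ";".join(f"{a}-{b}" for a, b in rec.mapped_fragments),
                    ",".join(rec.go_terms),
                ]
            )


def curate(
    table: OrthologTable,
    design: SampleDesign,
    sequences: Mapping[str, str],
    annotations: Iterable[AnnotationRecord],
    params: CurationParams = CurationParams(),
) -> tuple[list[LocusRecord], list[DiscardEntry]]:
    """Full curation chain: single-copy -> ORF length -> annotation rules."""
    loci, d1 = select_single_copy(table, design)
    loci, d2 = orf_length_filter(loci, sequences, params)
    loci, d3 = annotation_clean(loci, annotations, params)
    return loci, d1 + d2 + d3
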