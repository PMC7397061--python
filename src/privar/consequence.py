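"""Transcript-aware SNV consequence annotation with HGVS naming.

Given a transcript's CDS geometry (ordered 1-based inclusive intervals in
transcription order) and a reference sequence, classify a single-
nucleotide substitution by its effect on the encoded protein and emit
HGVS c. and p. strings (e.g. ``c.1658G>A`` / ``p.(Arg553Gln)``).

Codons are assembled across exon boundaries; minus-strand alleles are
complemented into CDS orientation before codon substitution.  Only
substitutions are annotated — every candidate in the intended use case
is an SNV; indel and splice-region consequences are outside this
annotator's scope (the effect vocabulary still names the non-coding
classes so downstream reports can carry them).
"""

from __future__ import annotations

import enum
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

from .variants import Reference, VariantIOError, VariantRecord, _ref_slice


class ConsequenceError(ValueError):
    pass


class EffectClass(enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    STOP_LOSS = "stop_loss"
    START_LOSS = "start_loss"
    INTRONIC = "intronic"
    UTR_OR_NONCODING = "utr_or_noncoding"
    INTERGENIC = "intergenic"


#: Classes that alter the encoded protein sequence.
PROTEIN_CHANGING_CLASSES = frozenset(
    {EffectClass.MISSENSE, EffectClass.NONSENSE,
     EffectClass.STOP_LOSS, EffectClass.START_LOSS}
)

#: Ordering used when one variant hits several transcripts (higher = worse).
SEVERITY_RANK = {
    EffectClass.NONSENSE: 6,
    EffectClass.STOP_LOSS: 6,
    EffectClass.START_LOSS: 6,
    EffectClass.MISSENSE: 5,
    EffectClass.SYNONYMOUS: 4,
    EffectClass.INTRONIC: 3,
    EffectClass.UTR_OR_NONCODING: 2,
    EffectClass.INTERGENIC: 1,
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_protein_changing(effect) -> bool:
    """True for missense, nonsense, stop-loss and start-loss effects.

    Accepts an :class:`EffectClass` or a :class:`CodingEffect`.
    """
    if isinstance(effect, CodingEffect):
        effect = effect.effect_class
    if not isinstance(effect, EffectClass):
        raise ConsequenceError(f"not an effect class: {effect!r}")
    return effect in PROTEIN_CHANGING_CLASSES


@dataclass(frozen=True)
class TranscriptModel:
    """CDS geometry of one transcript.

    ``cds_intervals`` are 1-based inclusive ``(start, end)`` pairs with
    ``start <= end``, given in transcription order: ascending genomic
    coordinates on the plus strand, descending on the minus strand.
    Total CDS length must be a multiple of 3.
    """

    transcript_id: str
    gene: str
    contig: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    codon_table_id: int = 1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ConsequenceError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.cds_intervals:
            raise ConsequenceError(f"{self.transcript_id}: no CDS intervals")
        ivs = sorted(self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ConsequenceError(
                    f"{self.transcript_id}: overlapping CDS intervals"
                )
        for s, e in ivs:
            if s < 1 or e < s:
                raise ConsequenceError(
                    f"{self.transcript_id}: bad interval ({s}, {e})"
                )
        expected = ivs if self.strand == "+" else ivs[::-1]
        if list(self.cds_intervals) != expected:
            raise ConsequenceError(
                f"{self.transcript_id}: intervals not in transcription order"
            )
        if self.cds_length % 3 != 0:
            raise ConsequenceError(
                f"{self.transcript_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def n_codons(self) -> int:
        return self.cds_length // 3

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (min, max) covered by the transcript's CDS footprint."""
        return (min(s for s, _ in self.cds_intervals),
                max(e for _, e in self.cds_intervals))

    def cds_sequence(self, reference: Reference) -> str:
        """Spliced CDS in transcription (sense) orientation."""
        parts = []
        for s, e in self.cds_intervals:
            chunk = _ref_slice(reference, self.contig, s, e)
            parts.append(chunk if self.strand == "+" else _revcomp(chunk))
        return "".join(parts)


def genomic_to_cds(tm: TranscriptModel, genomic_pos: int) -> int | None:
    """1-based CDS coordinate of a genomic position, or None if non-coding.

    On the plus strand CDS bases are counted from the CDS start forward;
    on the minus strand from the CDS (genomic) end backwards.
    """
    offset = 0
    for s, e in tm.cds_intervals:
        if s <= genomic_pos <= e:
            if tm.strand == "+":
                return offset + (genomic_pos - s) + 1
            return offset + (e - genomic_pos) + 1
        offset += e - s + 1
    return None


def cds_to_genomic(tm: TranscriptModel, cds_pos: int) -> int:
    """Inverse of :func:`genomic_to_cds` over 1..cds_length."""
    if not 1 <= cds_pos <= tm.cds_length:
        raise ConsequenceError(
            f"CDS position {cds_pos} outside 1..{tm.cds_length} "
            f"for {tm.transcript_id}"
        )
    remaining = cds_pos
    for s, e in tm.cds_intervals:
        size = e - s + 1
        if remaining <= size:
            return s + remaining - 1 if tm.strand == "+" else e - remaining + 1
        remaining -= size
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class CodingEffect:
    """Classified consequence of an SNV inside a CDS."""

    transcript_id: str
    gene: str
    cds_pos: int
    ref_codon: str
    alt_codon: str
    ref_aa: str  # 3-letter, "Ter" for stop
    alt_aa: str
    residue_index: int
    effect_class: EffectClass

    def __post_init__(self) -> None:
        if self.residue_index != (self.cds_pos + 2) // 3:
            raise ConsequenceError(
                f"residue_index {self.residue_index} inconsistent with "
                f"cds_pos {self.cds_pos}"
            )
        if (self.ref_aa == self.alt_aa) != (self.effect_class is EffectClass.SYNONYMOUS):
            raise ConsequenceError("effect class inconsistent with amino-acid pair")
        if (self.alt_aa == "Ter" and self.ref_aa != "Ter"
                and self.effect_class is not EffectClass.NONSENSE):
            raise ConsequenceError("stop-gain must be classed nonsense")

    @property
    def c_hgvs(self) -> str:
        """HGVS cDNA name, alleles in CDS orientation (e.g. ``c.1658G>A``)."""
        pos_in_codon = (self.cds_pos - 1) % 3
        return (
            f"c.{self.cds_pos}"
            f"{self.ref_codon[pos_in_codon]}>{self.alt_codon[pos_in_codon]}"
        )

    def p_hgvs(self, parenthesized: bool = True, ter_symbol: str = "Ter") -> str:
        """HGVS protein name, e.g. ``p.(Arg553Gln)`` or ``p.Glu799*``.

        The predicted (parenthesized) form is the default; both the
        parenthesized and plain spellings are in common use, as are
        ``Ter`` and ``*`` for a stop gain.
        """
        ref = self.ref_aa
        alt = "=" if self.effect_class is EffectClass.SYNONYMOUS else self.alt_aa
        if ter_symbol == "*":
            ref = "*" if ref == "Ter" else ref
            alt = "*" if alt == "Ter" else alt
        body = f"{ref}{self.residue_index}{alt}"
        return f"p.({body})" if parenthesized else f"p.{body}"


def _translate_codon(codon: str, table_id: int) -> str:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    if codon in table.stop_codons:
        return "Ter"
    try:
        return seq3(table.forward_table[codon])
    except KeyError:
        raise ConsequenceError(f"cannot translate codon {codon!r}") from None


def annotate_snv(
    tm: TranscriptModel, reference: Reference, variant: VariantRecord
) -> CodingEffect | EffectClass:
    """Annotate a normalized SNV against one transcript.

    Returns a :class:`CodingEffect` when the variant falls in the CDS;
    otherwise ``EffectClass.INTRONIC`` (inside the transcript's CDS
    footprint) or ``EffectClass.INTERGENIC``.

    Raises
    ------
    ConsequenceError
        If the variant is not an SNV, lies on another contig being
        irrelevant is fine (returns INTERGENIC), or its REF allele
        disagrees with the reference at the locus.
    """
    if not variant.is_snv:
        raise ConsequenceError(f"not an SNV: {variant}")
    if variant.contig != tm.contig:
        return EffectClass.INTERGENIC

    ref_base = _ref_slice(reference, variant.contig, variant.pos, variant.pos)
    if ref_base != variant.ref:
        raise VariantIOError(
            f"REF mismatch at {variant.contig}:{variant.pos}: variant has "
            f"{variant.ref!r}, reference has {ref_base!r}"
        )

    cds_pos = genomic_to_cds(tm, variant.pos)
    if cds_pos is None:
        lo, hi = tm.span
        return EffectClass.INTRONIC if lo <= variant.pos <= hi else EffectClass.INTERGENIC

    # Alleles in CDS (sense-strand) orientation.
    if tm.strand == "+":
        cds_ref, cds_alt = variant.ref, variant.alt
    else:
        cds_ref, cds_alt = _revcomp(variant.ref), _revcomp(variant.alt)

    residue = (cds_pos + 2) // 3
    pos_in_codon = (cds_pos - 1) % 3
    codon_cds_start = (residue - 1) * 3 + 1
    ref_codon = "".join(
        _ref_slice(reference, tm.contig, g, g) if tm.strand == "+"
        else _revcomp(_ref_slice(reference, tm.contig, g, g))
        for g in (cds_to_genomic(tm, codon_cds_start + k) for k in range(3))
    )
    assert ref_codon[pos_in_codon] == cds_ref
    alt_codon = ref_codon[:pos_in_codon] + cds_alt + ref_codon[pos_in_codon + 1 :]

    ref_aa = _translate_codon(ref_codon, tm.codon_table_id)
    alt_aa = _translate_codon(alt_codon, tm.codon_table_id)

    if ref_aa == alt_aa:
        klass = EffectClass.SYNONYMOUS
    elif alt_aa == "Ter":
        klass = EffectClass.NONSENSE
    elif ref_aa == "Ter":
        klass = EffectClass.STOP_LOSS
    elif residue == 1 and ref_aa == "Met":
        klass = EffectClass.START_LOSS
    else:
        klass = EffectClass.MISSENSE

    return CodingEffect(
        transcript_id=tm.transcript_id,
        gene=tm.gene,
        cds_pos=cds_pos,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        residue_index=residue,
        effect_class=klass,
    )


def effect_class_of(effect: CodingEffect | EffectClass) -> EffectClass:
    return effect.effect_class if isinstance(effect, CodingEffect) else effect


def annotate_variant(
    transcripts: Sequence[TranscriptModel],
    reference: Reference,
    variant: VariantRecord,
) -> CodingEffect | EffectClass:
    """Annotate against every transcript; report the most severe effect.

    With no transcripts on the variant's contig the class is intergenic.
    Ties in severity break deterministically by transcript id.
    """
    best: CodingEffect | EffectClass = EffectClass.INTERGENIC
    best_rank = (SEVERITY_RANK[EffectClass.INTERGENIC], "")
    for tm in sorted(transcripts, key=lambda t: t.transcript_id):
        eff = annotate_snv(tm, reference, variant)
        rank = (SEVERITY_RANK[effect_class_of(eff)], "")
        if rank[0] > best_rank[0]:
            best, best_rank = eff, rank
    return best


class TranscriptIndex:
    """Per-contig interval lookup so cohort-scale annotation stays linear.

    Transcripts are bucketed by contig and looked up by CDS-footprint
    overlap with a sorted sweep; suitable for thousands of variants
    against tens of transcripts per contig.
    """

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self._by_contig: dict[str, list[TranscriptModel]] = {}
        for tm in transcripts:
            self._by_contig.setdefault(tm.contig, []).append(tm)
        self._starts: dict[str, list[int]] = {}
        for contig, tms in self._by_contig.items():
            tms.sort(key=lambda t: t.span)
            self._starts[contig] = [t.span[0] for t in tms]

    def overlapping(self, contig: str, pos: int) -> list[TranscriptModel]:
        tms = self._by_contig.get(contig, [])
        starts = self._starts.get(contig, [])
        hi = bisect_right(starts, pos)
        return [t for t in tms[:hi] if t.span[0] <= pos <= t.span[1]]

    def annotate(
        self, reference: Reference, variant: VariantRecord
    ) -> CodingEffect | EffectClass:
        hits = self.overlapping(variant.contig, variant.pos)
        if not hits:
            return EffectClass.INTERGENIC
        return annotate_variant(hits, reference, variant)


# ---------------------------------------------------------------------------
# gene-model file readers / writer


def read_gene_models_bed(path: str | Path) -> list[TranscriptModel]:
    """Read a 6-column BED-like TSV: contig, start, end, transcript, strand, gene.

    Coordinates are 1-based inclusive (matching the rest of the package,
    not UCSC BED half-open).  Rows sharing a transcript id form its CDS
    intervals; they are sorted into transcription order per strand.
    """
    rows: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            contig, start, end, tid, strand, gene = line.rstrip("\n").split("\t")[:6]
            entry = rows.setdefault(
                tid, {"contig": contig, "strand": strand, "gene": gene, "ivs": []}
            )
            entry["ivs"].append((int(start), int(end)))
    models = []
    for tid, entry in rows.items():
        ivs = sorted(entry["ivs"])
        if entry["strand"] == "-":
            ivs = ivs[::-1]
        models.append(
            TranscriptModel(tid, entry["gene"], entry["contig"],
                            entry["strand"], tuple(ivs))
        )
    return sorted(models, key=lambda t: t.transcript_id)


def read_gene_models_gff3(path: str | Path) -> list[TranscriptModel]:
    """Read transcript CDS models from a GFF3 with CDS features.

    CDS features are grouped by their ``Parent`` (mRNA) attribute; the
    gene symbol is taken from the mRNA's ``gene`` attribute or its
    parent gene's ``Name``/``ID``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for mrna in db.features_of_type("mRNA"):
        cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
        if not cds:
            continue
        ivs = sorted((c.start, c.end) for c in cds)
        strand = mrna.strand
        if strand == "-":
            ivs = ivs[::-1]
        gene = mrna.attributes.get("gene", [None])[0]
        if gene is None:
            parents = list(db.parents(mrna, featuretype="gene"))
            if parents:
                p = parents[0]
                gene = p.attributes.get("Name", p.attributes.get("ID", ["?"]))[0]
            else:
                gene = mrna.id
        models.append(TranscriptModel(mrna.id, gene, mrna.seqid, strand, tuple(ivs)))
    return sorted(models, key=lambda t: t.transcript_id)


def read_gene_models(path: str | Path) -> list[TranscriptModel]:
    """Dispatch on extension: .gff3/.gff -> GFF3, otherwise BED-like TSV."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gff3", ".gff"):
        return read_gene_models_gff3(path)
    return read_gene_models_bed(path)


def write_gene_models_gff3(models: Sequence[TranscriptModel], path: str | Path) -> None:
    """Emit gene/mRNA/CDS features for a list of transcript models."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tm in sorted(models, key=lambda t: t.transcript_id):
            lo, hi = tm.span
            gene_id = f"gene-{tm.gene}"
            fh.write(
                f"{tm.contig}\tprivar\tgene\t{lo}\t{hi}\t.\t{tm.strand}\t.\t"
                f"ID={gene_id};Name={tm.gene}\n"
            )
            fh.write(
                f"{tm.contig}\tprivar\tmRNA\t{lo}\t{hi}\t.\t{tm.strand}\t.\t"
                f"ID={tm.transcript_id};Parent={gene_id};gene={tm.gene}\n"
            )
            phase = 0
            for s, e in tm.cds_intervals:
                fh.write(
                    f"{tm.contig}\tprivar\tCDS\t{s}\t{e}\t.\t{tm.strand}\t{phase}\t"
                    f"ID=cds-{tm.transcript_id};Parent={tm.transcript_id}\n"
                )
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
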