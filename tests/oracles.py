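"""Independent brute-force oracles used across the test suite.

Each oracle recomputes a result by a deliberately different route from
the implementation under test: plain-text VCF parsing, whole-sequence
comparison for normalization, exhaustive per-variant scans for the
cohort filter, whole-CDS translate-and-diff for consequence calls, and
rule-table enumeration for trio Mendelian checks.
"""

from __future__ import annotations

from Bio.Seq import Seq

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# VCF text parsing (line-by-line, no pysam)


def parse_vcf_text(path) -> tuple[list[str], list[tuple]]:
    """Hand parser: returns (samples, rows) with one row per ALT allele.

    Row = (contig, pos, ref, alt, calls) where calls are alt-allele
    counts (-1 = missing) decoded directly from the GT strings.
    """
    samples: list[str] = []
    rows: list[tuple] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            contig, pos, _, ref, alt_field = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
            fmt = fields[8].split(":")
            gt_idx = fmt.index("GT")
            gts = [f.split(":")[gt_idx] for f in fields[9:]]
            for k, alt in enumerate(alt_field.split(","), start=1):
                calls = []
                for gt in gts:
                    alleles = gt.replace("|", "/").split("/")
                    if any(a == "." for a in alleles):
                        calls.append(-1)
                    else:
                        calls.append(sum(1 for a in alleles if int(a) == k))
                rows.append((contig, pos, ref, alt, tuple(calls)))
    return samples, rows


# ---------------------------------------------------------------------------
# normalization by whole-sequence comparison


def normalize_oracle(seq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Leftmost parsimonious representation via full-sequence diff.

    Applies the variant to the sequence, trims the maximal common
    suffix then prefix of the two strings, and left-pads with the
    preceding reference base when an allele empties.
    """
    mutated = seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]
    i, j = len(seq), len(mutated)
    while i > 0 and j > 0 and seq[i - 1] == mutated[j - 1]:
        i -= 1
        j -= 1
    k = 0
    while k < min(i, j) and seq[k] == mutated[k]:
        k += 1
    r, a = seq[k:i], mutated[k:j]
    p = k + 1
    if not r or not a:
        p -= 1
        r, a = seq[p - 1] + r, seq[p - 1] + a
    return p, r, a


# ---------------------------------------------------------------------------
# cohort filter by exhaustive scan


def filter_scan_oracle(variants, calls, sample_status, model: str,
                       missing_control: str = "ref") -> list:
    """Per-variant python-loop scan; model is 'het' or 'hom'."""
    required = 1 if model == "het" else 2
    out = []
    for i, v in enumerate(variants):
        ok = True
        for j, status in enumerate(sample_status):
            c = calls[i][j]
            if status == "case":
                if c != required:
                    ok = False
            elif status == "control":
                if missing_control == "ref":
                    if c not in (0, -1):
                        ok = False
                else:
                    if c != 0:
                        ok = False
        if ok:
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# consequence by whole-CDS translate-and-diff


def cds_positions(intervals, strand: str) -> list[int]:
    """Genomic position of every CDS base, in transcription order."""
    positions: list[int] = []
    for s, e in intervals:
        positions.extend(range(s, e + 1) if strand == "+" else range(e, s - 1, -1))
    return positions


def translate_diff_oracle(intervals, strand, seq, variant_pos, variant_alt):
    """Classify an SNV by translating the whole mutant CDS and diffing.

    Returns ``(klass, ref_aa, alt_aa, residue)`` with 1-letter amino
    acids ('*' = stop) or ``(klass, None, None, None)`` for non-coding.
    ``klass`` is one of synonymous/missense/nonsense/stop_loss/
    start_loss/intronic/intergenic.
    """
    positions = cds_positions(intervals, strand)
    if variant_pos not in positions:
        lo = min(s for s, _ in intervals)
        hi = max(e for _, e in intervals)
        return ("intronic" if lo <= variant_pos <= hi else "intergenic",
                None, None, None)
    idx = positions.index(variant_pos)
    bases = [seq[p - 1] for p in positions]
    if strand == "-":
        bases = [COMPLEMENT[b] for b in bases]
    ref_cds = "".join(bases)
    alt_base = variant_alt if strand == "+" else COMPLEMENT[variant_alt]
    alt_cds = ref_cds[:idx] + alt_base + ref_cds[idx + 1 :]
    ref_prot = str(Seq(ref_cds).translate())
    alt_prot = str(Seq(alt_cds).translate())
    diffs = [r for r, (x, y) in enumerate(zip(ref_prot, alt_prot), start=1) if x != y]
    if not diffs:
        return ("synonymous", ref_prot[idx // 3], alt_prot[idx // 3], idx // 3 + 1)
    (residue,) = diffs
    x, y = ref_prot[residue - 1], alt_prot[residue - 1]
    if y == "*":
        klass = "nonsense"
    elif x == "*":
        klass = "stop_loss"
    elif residue == 1 and x == "M":
        klass = "start_loss"
    else:
        klass = "missense"
    return (klass, x, y, residue)


# ---------------------------------------------------------------------------
# dominant-model trio rules by direct enumeration


def trio_violations_oracle(sire_g, dam_g, child_g, child_phenotype,
                           allow_nonpenetrant=False) -> set[str]:
    """Violation kinds for one child given parental genotypes (None = untyped)."""
    out = set()
    if child_g is None:
        return out
    if child_phenotype == "affected" and child_g == 0:
        out.add("affected_noncarrier")
    if child_phenotype == "unaffected" and child_g >= 1 and not allow_nonpenetrant:
        out.add("unaffected_carrier")
    gametes = {0: {0}, 1: {0, 1}, 2: {1}, None: {0, 1}}
    possible = {a + b for a in gametes[sire_g] for b in gametes[dam_g]}
    if child_g not in possible:
        out.add("mendelian")
    return out
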