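"""Candidate ranking with an explicit, configurable linear score.

In the original discovery setting the choice among the surviving
protein-changing variants was expert biological judgment about the
altered genes.  That judgment is formalized here — not laundered as
computation — as a transparent linear score over three terms:

``score = w_severity * severity_rank + w_conservation * fraction + w_prior * in_gene_list``

with the knowledge prior OFF by default.  Without a prior, a stop-gain
outranks any missense; a candidate in a user-supplied gene list rises
only when the prior weight is turned on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .consequence import EffectClass


class PrioritizeError(ValueError):
    pass


#: Severity ranks of effect classes for scoring (coarser than the
#: annotation-time SEVERITY_RANK used for transcript tie-breaks).
SCORE_SEVERITY = {
    EffectClass.NONSENSE: 3,
    EffectClass.STOP_LOSS: 3,
    EffectClass.START_LOSS: 3,
    EffectClass.MISSENSE: 2,
}

DEFAULT_WEIGHTS: dict[str, float] = {
    "severity": 1.0,
    "conservation": 0.5,
    "prior": 0.0,
}


@dataclass(frozen=True)
class CandidateRow:
    """One surviving protein-changing variant, ready for ranking."""

    gene: str
    contig: str
    pos: int
    ref: str
    alt: str
    effect_class: EffectClass
    c_hgvs: str = ""
    p_hgvs: str = ""
    conservation: float | None = None
    in_gene_list: bool = False
    score: float = 0.0


def score_candidate(row: CandidateRow, weights: Mapping[str, float]) -> float:
    sev = SCORE_SEVERITY.get(row.effect_class, 0)
    cons = row.conservation if row.conservation is not None else 0.0
    return (
        weights["severity"] * sev
        + weights["conservation"] * cons
        + weights["prior"] * (1.0 if row.in_gene_list else 0.0)
    )


def rank_candidates(
    rows: Sequence[CandidateRow],
    weights: Mapping[str, float] | None = None,
    gene_list: Iterable[str] = (),
) -> list[CandidateRow]:
    """Order candidates by descending score, deterministically.

    The sort is stable with ties broken lexicographically by
    ``(gene, contig, pos)``, so the ranking does not depend on the input
    order of equal-scoring rows.
    """
    if not rows:
        raise PrioritizeError("no candidate rows to rank")
    merged = dict(DEFAULT_WEIGHTS)
    if weights:
        unknown = set(weights) - set(DEFAULT_WEIGHTS)
        if unknown:
            raise PrioritizeError(f"unknown weight keys: {sorted(unknown)}")
        merged.update(weights)
    genes = set(gene_list)

    scored = [
        replace(r, in_gene_list=r.gene in genes or r.in_gene_list)
        for r in rows
    ]
    scored = [replace(r, score=score_candidate(r, merged)) for r in scored]
    return sorted(scored, key=lambda r: (-r.score, r.gene, r.contig, r.pos))


def write_candidates_tsv(rows: Sequence[CandidateRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "rank\tgene\tcontig\tpos\tref\talt\teffect\tc_hgvs\tp_hgvs\t"
            "conservation\tin_gene_list\tscore\n"
        )
        for i, r in enumerate(rows, start=1):
            cons = "" if r.conservation is None else f"{r.conservation:.4g}"
            fh.write(
                f"{i}\t{r.gene}\t{r.contig}\t{r.pos}\t{r.ref}\t{r.alt}\t"
                f"{r.effect_class.value}\t{r.c_hgvs}\t{r.p_hgvs}\t{cons}\t"
                f"{int(r.in_gene_list)}\t{r.score:.4g}\n"
            )
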