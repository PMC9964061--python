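"""Candidate mutation filtering and splice-site annotation.

Inside the mapped interval the causal EMS lesion is homozygous in the
mutant pool, so candidate positions are those where the mutant pool is
(nearly) fixed for a non-reference base.  The list is then thinned by
two biological filters: substitutions shared with sibling mutant lines
or the non-reference parental accession are pre-existing polymorphisms,
and EMS overwhelmingly induces G/C-to-A/T transitions.  Survivors are
annotated against gene models, with special care for the canonical
splice dinucleotides — a hit at position -1 of an acceptor site (the
intron's last base, the G of the AG) is a classic loss-of-function
lesion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .core import GeneModel, MarkerTrack
from .mapping import CandidateInterval

EMS_TRANSITIONS = {("G", "A"), ("C", "T")}

DEFAULT_MIN_ALT_FREQ = 0.9
DEFAULT_MIN_DEPTH = 10
DEFAULT_SPLICE_WINDOW = 2

ANNOTATION_PRIORITY = (
    "splice_acceptor",
    "splice_donor",
    "exonic",
    "intronic",
    "intergenic",
)


@dataclass(frozen=True)
class CandidateVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    mut_alt_freq: float
    shared: bool = False
    annotation: str = "intergenic"
    gene_id: str = ""
    splice_offset: int | None = None

    @property
    def is_transition(self) -> bool:
        """True for the EMS-type G-to-A / C-to-T substitutions."""
        return (self.ref, self.alt) in EMS_TRANSITIONS


def list_nonref_positions(
    track: MarkerTrack,
    interval: CandidateInterval,
    min_alt_freq: float = DEFAULT_MIN_ALT_FREQ,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> list[CandidateVariant]:
    """Positions in the interval where the mutant pool is near-fixed non-reference.

    A candidate needs mutant-pool depth >= ``min_depth`` and alt-read
    fraction >= ``min_alt_freq`` — the homozygosity expected of the
    causal site and anything tightly linked to it.
    """
    if track.chrom != interval.chrom:
        return []
    out: list[CandidateVariant] = []
    depth = track.mut_depth
    for i in range(len(track)):
        pos = int(track.pos[i])
        if pos < interval.start_pos or pos > interval.end_pos:
            continue
        d = int(depth[i])
        if d < min_depth:
            continue
        freq = int(track.mut_alt[i]) / d
        if freq >= min_alt_freq:
            out.append(
                CandidateVariant(
                    chrom=track.chrom,
                    pos=pos,
                    ref=str(track.ref[i]),
                    alt=str(track.alt[i]),
                    mut_alt_freq=freq,
                )
            )
    return out


def exclude_shared(
    candidates: Iterable[CandidateVariant],
    control_sets: Sequence[set[tuple[str, int, str, str]]],
) -> list[CandidateVariant]:
    """Flag candidates whose exact (chrom, pos, ref, alt) occurs in any control set.

    Matching is allele-exact: a control variant at the same position
    with a different alternative base is an independent lesion and does
    not flag the candidate.  Returns all candidates with ``shared``
    set; use :func:`drop_shared` for the filtered view.
    """
    merged: set[tuple[str, int, str, str]] = set()
    for s in control_sets:
        merged |= s
    return [
        replace(c, shared=(c.chrom, c.pos, c.ref, c.alt) in merged)
        for c in candidates
    ]


def drop_shared(candidates: Iterable[CandidateVariant]) -> list[CandidateVariant]:
    return [c for c in candidates if not c.shared]


def filter_transitions(candidates: Iterable[CandidateVariant]) -> list[CandidateVariant]:
    """Keep only G-to-A / C-to-T changes (the EMS mutation spectrum)."""
    return [c for c in candidates if c.is_transition]


def _classify_against_model(
    pos: int, model: GeneModel, acceptor_window: int, donor_window: int
) -> tuple[str, int | None]:
    """Annotation and splice offset of ``pos`` within one gene model.

    Offsets follow transcription orientation: +1 is the intron's first
    base (donor side), -1 its last base (acceptor side).
    """
    lo, hi = model.span
    if pos < lo or pos > hi:
        return "intergenic", None
    for a, b in model.exons:
        if a <= pos <= b:
            return "exonic", None
    for a, b in model.introns:
        if not (a <= pos <= b):
            continue
        if model.strand == "+":
            donor_off = pos - a + 1  # +1 at the intron's 5' (left) end
            acceptor_off = pos - b - 1  # -1 at the 3' (right) end
        else:
            donor_off = b - pos + 1  # transcription runs right-to-left
            acceptor_off = a - pos - 1
        if -acceptor_off <= acceptor_window:
            return "splice_acceptor", acceptor_off
        if donor_off <= donor_window:
            return "splice_donor", donor_off
        # plain intronic: report the signed distance to the nearest
        # boundary (acceptor side wins a tie, being the conserved end)
        if -acceptor_off <= donor_off:
            return "intronic", acceptor_off
        return "intronic", donor_off
    return "intergenic", None  # between this model's span gaps (none for valid models)


def annotate_variant(
    variant: CandidateVariant,
    gene_models: Sequence[GeneModel],
    acceptor_window: int = DEFAULT_SPLICE_WINDOW,
    donor_window: int = DEFAULT_SPLICE_WINDOW,
) -> CandidateVariant:
    """Annotate one variant against all gene models on its chromosome.

    When models overlap, the highest-priority classification wins
    (splice_acceptor > splice_donor > exonic > intronic > intergenic),
    then lexicographically smallest gene id for determinism.
    """
    best = ("intergenic", None, "")
    best_rank = ANNOTATION_PRIORITY.index("intergenic")
    for model in sorted(gene_models, key=lambda m: m.gene_id):
        if model.chrom != variant.chrom:
            continue
        annotation, offset = _classify_against_model(
            variant.pos, model, acceptor_window, donor_window
        )
        rank = ANNOTATION_PRIORITY.index(annotation)
        if rank < best_rank:
            best = (annotation, offset, model.gene_id if annotation != "intergenic" else "")
            best_rank = rank
    return replace(
        variant, annotation=best[0], splice_offset=best[1], gene_id=best[2]
    )


def annotate_all(
    candidates: Iterable[CandidateVariant],
    gene_models: Sequence[GeneModel],
    acceptor_window: int = DEFAULT_SPLICE_WINDOW,
    donor_window: int = DEFAULT_SPLICE_WINDOW,
) -> list[CandidateVariant]:
    return [
        annotate_variant(c, gene_models, acceptor_window, donor_window)
        for c in candidates
    ]


def candidate_pipeline(
    track: MarkerTrack,
    interval: CandidateInterval,
    control_sets: Sequence[set[tuple[str, int, str, str]]] = (),
    gene_models: Sequence[GeneModel] = (),
    min_alt_freq: float = DEFAULT_MIN_ALT_FREQ,
    min_depth: int = DEFAULT_MIN_DEPTH,
    acceptor_window: int = DEFAULT_SPLICE_WINDOW,
    donor_window: int = DEFAULT_SPLICE_WINDOW,
) -> list[CandidateVariant]:
    """Full chain: list non-reference positions, drop shared, keep EMS
    transitions, annotate; sorted by (annotation priority, position)."""
    cands = list_nonref_positions(track, interval, min_alt_freq, min_depth)
    cands = drop_shared(exclude_shared(cands, control_sets))
    cands = filter_transitions(cands)
    cands = annotate_all(cands, gene_models, acceptor_window, donor_window)
    return sorted(
        cands, key=lambda c: (ANNOTATION_PRIORITY.index(c.annotation), c.pos)
    )
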