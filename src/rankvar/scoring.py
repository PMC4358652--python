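"""Pathogenicity scoring.

Every annotated variant receives an integer prioritization score built
from a category base score plus small evidence adjustments:

* coding categories — nonsense/frameshift (100), start/stop loss (80),
  missense (50), in-frame indel (40), synonymous (10);
* splice categories — essential splice site (90, the two first intronic
  bases of a donor or acceptor), close intron–exon boundary (70, donor
  window −3..+6 / acceptor window −12..+2), deep intronic (25) — the two
  non-canonical categories require a consensus of at least two of three
  splice predictors (MaxEntScan, NNSplice, SpliceSiteFinder) reporting a
  significant score loss (−10%, −5%, −15% respectively);
* a +5 conservation adjustment when phastCons exceeds 0.95 (not applied
  to frameshift, in-frame or known mutations), and +5 per deleterious
  protein prediction (SIFT, PolyPhen-2) for missense variants;
* a known-mutation override (110, never adjusted) when dbSNP clinical
  significance reports the variant as pathogenic/probable-pathogenic or
  the user supplies it in a known-mutation list.

A variant is scored on every transcript through both the coding and the
splice pathway, and the most pathogenic effect is retained — e.g. an SNV
on the last exonic base may score as a missense or as a splice change,
whichever is higher.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence

from .annotation import TranscriptAnnotation, select_representative

logger = logging.getLogger(__name__)


class Category:
    KNOWN = "known mutation"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    ESSENTIAL_SPLICE = "essential splice"
    START_LOSS = "start loss"
    STOP_LOSS = "stop loss"
    CLOSE_SPLICE = "close splice"
    MISSENSE = "missense"
    IN_FRAME = "in-frame"
    DEEP_SPLICE = "deep splice"
    SYNONYMOUS = "synonymous"
    NONE = "none"


#: Categories eligible for the +5 conservation adjustment.
CONSERVATION_ADJUSTED = frozenset(
    {
        Category.NONSENSE,
        Category.ESSENTIAL_SPLICE,
        Category.START_LOSS,
        Category.STOP_LOSS,
        Category.CLOSE_SPLICE,
        Category.MISSENSE,
        Category.DEEP_SPLICE,
        Category.SYNONYMOUS,
    }
)


@dataclass
class ScoringConfig:
    """Score table and splice-rule parameters; field names double as the
    user-facing override option names."""

    S_Known: int = 110
    S_Nonsense: int = 100
    S_Fs: int = 100
    S_EssentialSplice: int = 90
    S_StartLoss: int = 80
    S_StopLoss: int = 80
    S_CloseSplice: int = 70
    S_Missense: int = 50
    S_Inframe: int = 40
    S_DeepSplice: int = 25
    S_Synonymous: int = 10
    adjustment_step: int = 5
    phastcons_cutoff: float = 0.95
    #: significant percent-loss thresholds, one per predictor
    mes_threshold: float = -10.0
    nns_threshold: float = -5.0
    ssf_threshold: float = -15.0
    splice_consensus_min: int = 2
    #: close-boundary windows, counted in bases from the splice site
    donor_window: tuple[int, int] = (-3, 6)  # (exonic, intronic) extent
    acceptor_window: tuple[int, int] = (-2, 12)

    def base_score(self, category: str) -> int:
        return {
            Category.KNOWN: self.S_Known,
            Category.NONSENSE: self.S_Nonsense,
            Category.FRAMESHIFT: self.S_Fs,
            Category.ESSENTIAL_SPLICE: self.S_EssentialSplice,
            Category.START_LOSS: self.S_StartLoss,
            Category.STOP_LOSS: self.S_StopLoss,
            Category.CLOSE_SPLICE: self.S_CloseSplice,
            Category.MISSENSE: self.S_Missense,
            Category.IN_FRAME: self.S_Inframe,
            Category.DEEP_SPLICE: self.S_DeepSplice,
            Category.SYNONYMOUS: self.S_Synonymous,
            Category.NONE: 0,
        }[category]

    def override(self, **kwargs) -> "ScoringConfig":
        known = {f.name for f in fields(self)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown scoring option(s): {', '.join(sorted(unknown))}")
        return replace(self, **kwargs)


_CODING_CATEGORY = {
    "nonsense": Category.NONSENSE,
    "frameshift": Category.FRAMESHIFT,
    "start loss": Category.START_LOSS,
    "stop loss": Category.STOP_LOSS,
    "missense": Category.MISSENSE,
    "in-frame": Category.IN_FRAME,
    "synonymous": Category.SYNONYMOUS,
}


@dataclass
class ScoredVariant:
    """A variant's chosen representative annotation and final score."""

    variant_id: str
    representative: Optional[TranscriptAnnotation]
    category: str
    base_score: int
    adjustment: int
    final_score: int
    effect_provenance: str  # "coding" | "splice" | "known" | "none"
    annotation_analysis: str = "Yes"


def splice_consensus(
    mes_delta: Optional[float],
    nns_delta: Optional[float],
    ssf_delta: Optional[float],
    config: ScoringConfig | None = None,
) -> bool:
    """Two-of-three splice-predictor consensus on a significant loss.

    A predictor votes when its percent score change is at or below its
    threshold (MaxEntScan −10%, NNSplice −5%, SpliceSiteFinder −15%);
    absent predictors contribute no vote.
    """
    config = config or ScoringConfig()
    votes = 0
    for delta, threshold in (
        (mes_delta, config.mes_threshold),
        (nns_delta, config.nns_threshold),
        (ssf_delta, config.ssf_threshold),
    ):
        if delta is not None and delta <= threshold:
            votes += 1
    return votes >= config.splice_consensus_min


def splice_category(
    dist_nearest_ss: Optional[int],
    nearest_ss: Optional[str],
    location: str,
    consensus: bool,
    config: ScoringConfig | None = None,
) -> str:
    """Classify a position relative to its nearest splice site.

    Distances are signed: positive = intronic side of the site, zero or
    negative = exonic side. Canonical-site positions (+1/+2 of either
    site) are *essential* regardless of predictor consensus; the close
    boundary windows and deep intronic positions require consensus.
    """
    config = config or ScoringConfig()
    if dist_nearest_ss is None:
        return Category.NONE
    if nearest_ss not in ("donor", "acceptor"):
        if location == "intron":
            logger.warning(
                "intronic variant with unknown nearest splice site; not scored for splicing"
            )
        return Category.NONE
    dist = dist_nearest_ss
    if dist in (1, 2):
        return Category.ESSENTIAL_SPLICE
    if not consensus:
        return Category.NONE
    exonic_extent, intronic_extent = (
        config.donor_window if nearest_ss == "donor" else config.acceptor_window
    )
    if exonic_extent <= dist <= intronic_extent:
        return Category.CLOSE_SPLICE
    if dist > intronic_extent and location == "intron":
        return Category.DEEP_SPLICE
    return Category.NONE


def sift_deleterious(ann: TranscriptAnnotation) -> bool:
    if ann.sift_pred is not None:
        p = ann.sift_pred.lower()
        return "deleterious" in p or "damaging" in p
    if ann.sift_weight is not None:
        return ann.sift_weight <= 0.05
    return False


def pph2_deleterious(ann: TranscriptAnnotation) -> bool:
    if ann.pph2_pred is None:
        return False
    p = ann.pph2_pred.lower()
    return "damaging" in p or "deleterious" in p


def adjustment(
    ann: TranscriptAnnotation, category: str, config: ScoringConfig | None = None
) -> int:
    """Evidence adjustment added to the category base score.

    +5 for genomic conservation (phastCons above the cutoff) in the
    eligible categories; missense additionally gains +5 per deleterious
    protein prediction. Known mutations, frameshift and in-frame indels
    are never adjusted. Missing predictors contribute 0.
    """
    config = config or ScoringConfig()
    step = config.adjustment_step
    adj = 0
    if category in CONSERVATION_ADJUSTED:
        if ann.phastcons is not None and ann.phastcons > config.phastcons_cutoff:
            adj += step
    if category == Category.MISSENSE:
        if sift_deleterious(ann):
            adj += step
        if pph2_deleterious(ann):
            adj += step
    return adj


def _pathway_scores(
    ann: TranscriptAnnotation, config: ScoringConfig
) -> tuple[tuple[str, int, int], tuple[str, int, int]]:
    """(category, base, adjustment) for the coding and splice pathways."""
    coding_cat = _CODING_CATEGORY.get(ann.coding_effect, Category.NONE)
    coding = (coding_cat, config.base_score(coding_cat), adjustment(ann, coding_cat, config))
    consensus = splice_consensus(
        ann.mes.effective_delta(),
        ann.nns.effective_delta(),
        ann.ssf.effective_delta(),
        config,
    )
    splice_cat = splice_category(
        ann.dist_nearest_ss, ann.nearest_ss, ann.location, consensus, config
    )
    splice = (splice_cat, config.base_score(splice_cat), adjustment(ann, splice_cat, config))
    return coding, splice


def transcript_score(ann: TranscriptAnnotation, config: ScoringConfig | None = None) -> int:
    """Final score of one annotation: max of its coding and splice pathways."""
    config = config or ScoringConfig()
    coding, splice = _pathway_scores(ann, config)
    return max(coding[1] + coding[2], splice[1] + splice[2])


def score_variant(
    annotations: Sequence[TranscriptAnnotation],
    config: ScoringConfig | None = None,
    known_variants: Optional[set[str]] = None,
) -> ScoredVariant:
    """Score one variant across all its transcript annotations.

    Each transcript is scored through both pathways and the most
    pathogenic (highest adjusted) effect is retained; known-mutation
    evidence on any transcript overrides everything with the flat
    known-mutation score. An empty annotation list yields score 0 with
    AnnotationAnalysis "No".
    """
    config = config or ScoringConfig()
    known_variants = known_variants or set()
    if not annotations:
        return ScoredVariant(
            variant_id="",
            representative=None,
            category=Category.NONE,
            base_score=0,
            adjustment=0,
            final_score=0,
            effect_provenance="none",
            annotation_analysis="No",
        )
    variant_id = annotations[0].variant_id

    is_known = variant_id in known_variants or any(
        a.is_known_pathogenic() for a in annotations
    )
    if is_known:
        scores = [config.S_Known] * len(annotations)
        rep = select_representative(annotations, scores)
        return ScoredVariant(
            variant_id=variant_id,
            representative=rep,
            category=Category.KNOWN,
            base_score=config.S_Known,
            adjustment=0,
            final_score=config.S_Known,
            effect_provenance="known",
        )

    per_tx: list[tuple[int, str, int, int, str]] = []
    for ann in annotations:
        coding, splice = _pathway_scores(ann, config)
        coding_final = coding[1] + coding[2]
        splice_final = splice[1] + splice[2]
        if coding_final >= splice_final:  # ties go to the coding effect
            per_tx.append((coding_final, coding[0], coding[1], coding[2], "coding"))
        else:
            per_tx.append((splice_final, splice[0], splice[1], splice[2], "splice"))

    scores = [t[0] for t in per_tx]
    rep = select_representative(annotations, scores)
    win = per_tx[annotations.index(rep)]
    final, category, base, adj, provenance = win
    if category == Category.NONE:
        provenance = "none"
    return ScoredVariant(
        variant_id=variant_id,
        representative=rep,
        category=category,
        base_score=base,
        adjustment=adj,
        final_score=final,
        effect_provenance=provenance,
    )


def score_all(
    annotation_map: dict[str, list[TranscriptAnnotation]],
    config: ScoringConfig | None = None,
    known_variants: Optional[set[str]] = None,
) -> dict[str, ScoredVariant]:
    """Score every variant of a non-redundant annotation map."""
    config = config or ScoringConfig()
    out: dict[str, ScoredVariant] = {}
    for vid, anns in annotation_map.items():
        sv = score_variant(anns, config, known_variants)
        if not anns:
            sv.variant_id = vid
        out[vid] = sv
    return out
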