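"""Joint DNA/RNA genotype matching and classification.

A variant seen in both assays of one individual is classified by the pair of
genotype states: heterozygous in DNA with homozygous-alternative RNA is
called allele-specific expression (ASE, only the alt allele is expressed);
homozygous-alternative DNA with heterozygous RNA is called an RNA-editing
event (RNAe).  Everything else is bucketed for QC (concordant,
discordant_other, one-assay-only, ineligible).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .variant_io import (
    GENOTYPE_STATES,
    GenotypeObservation,
    NormalizedVariant,
    variant_sort_key,
)

logger = logging.getLogger("omixlink")

JOINT_LABELS = (
    "ASE",
    "RNAe",
    "concordant",
    "discordant_other",
    "dna_only",
    "rna_only",
    "ineligible",
)


@dataclass
class JointState:
    """One site's matched DNA and RNA evidence plus its joint label."""

    variant: NormalizedVariant
    dna: str
    rna: str
    dna_depth: int | None = None
    dna_gq: float | None = None
    rna_depth: int | None = None
    rna_gq: float | None = None
    label: str | None = None


def _dedup(observations: list[GenotypeObservation]) -> dict[tuple, GenotypeObservation]:
    """Collapse duplicate keys within one assay: highest GQ, then depth, then
    first-seen."""
    best: dict[tuple, GenotypeObservation] = {}
    order: dict[tuple, int] = {}
    for i, obs in enumerate(observations):
        key = obs.variant.key
        if key not in best:
            best[key], order[key] = obs, i
            continue
        logger.warning("duplicate observation for %s (%s)", key, obs.source)
        cur = best[key]
        cand_rank = (
            obs.gq if obs.gq is not None else float("-inf"),
            obs.depth if obs.depth is not None else -1,
            -i,
        )
        cur_rank = (
            cur.gq if cur.gq is not None else float("-inf"),
            cur.depth if cur.depth is not None else -1,
            -order[key],
        )
        if cand_rank > cur_rank:
            best[key], order[key] = obs, i
    return best


def join_observations(
    dna_obs: list[GenotypeObservation],
    rna_obs: list[GenotypeObservation],
) -> list[JointState]:
    """Full outer join of one individual's DNA and RNA observations.

    Sites absent from one assay carry state ``missing`` on that side.  Output
    is sorted by (chrom, start, end, ref, alt) with natural chromosome order.
    Labels are left unset; see :func:`classify_joint_state`.
    """
    dna = _dedup(dna_obs)
    rna = _dedup(rna_obs)
    keys = set(dna) | set(rna)
    variants = {}
    for obs in list(dna.values()) + list(rna.values()):
        variants.setdefault(obs.variant.key, obs.variant)

    joint: list[JointState] = []
    for key in sorted(keys, key=lambda k: variant_sort_key(variants[k])):
        d = dna.get(key)
        r = rna.get(key)
        joint.append(
            JointState(
                variant=variants[key],
                dna=d.state if d else "missing",
                rna=r.state if r else "missing",
                dna_depth=d.depth if d else None,
                dna_gq=d.gq if d else None,
                rna_depth=r.depth if r else None,
                rna_gq=r.gq if r else None,
            )
        )
    return joint


def site_eligibility(joint: JointState, thresholds) -> bool:
    """Quality gate for ASE/RNAe calling.

    True iff both assays observed the site (state not ``missing``) and depth
    and genotype quality clear the per-assay minima on both sides.  Unknown
    evidence fails the gate unless ``thresholds.lenient_evidence`` is set.
    """
    if joint.dna == "missing" or joint.rna == "missing":
        return False
    lenient = getattr(thresholds, "lenient_evidence", False)

    def _ok(value, minimum) -> bool:
        if value is None:
            return lenient
        return value >= minimum

    return (
        _ok(joint.dna_depth, thresholds.min_depth)
        and _ok(joint.rna_depth, thresholds.min_depth)
        and _ok(joint.dna_gq, thresholds.min_gq)
        and _ok(joint.rna_gq, thresholds.min_gq)
    )


def classify_joint_state(dna: str, rna: str, eligible: bool) -> str:
    """Total, deterministic label for one (DNA state, RNA state) pair.

    Missing-pattern labels take precedence (a site absent from one assay is
    ``dna_only``/``rna_only`` regardless of the evidence gate, and absent
    from both is ``ineligible``); next the eligibility gate; then the
    genotype pair: (het, hom_alt) → ASE, (hom_alt, het) → RNAe, equal states
    → concordant, anything else → discordant_other.
    """
    if dna not in GENOTYPE_STATES or rna not in GENOTYPE_STATES:
        raise ValueError(f"unknown genotype state pair ({dna!r}, {rna!r})")
    if dna == "missing" and rna == "missing":
        return "ineligible"
    if rna == "missing":
        return "dna_only"
    if dna == "missing":
        return "rna_only"
    if not eligible:
        return "ineligible"
    if dna == "het" and rna == "hom_alt":
        return "ASE"
    if dna == "hom_alt" and rna == "het":
        return "RNAe"
    if dna == rna:
        return "concordant"
    return "discordant_other"


def label_joint_states(joint: list[JointState], thresholds) -> list[JointState]:
    """Apply eligibility and classification in place; returns the list."""
    for js in joint:
        js.label = classify_joint_state(js.dna, js.rna, site_eligibility(js, thresholds))
    return joint
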