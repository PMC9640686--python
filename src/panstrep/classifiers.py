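"""Rule-based protein classification from domain-hit tables.

All classifiers operate on the multiset of Pfam/SMART domain hits per
protein and are order-independent:

* sigma factors: a protein is a sigma-70-family factor iff it carries
  the Sigma70_r2 domain (PF04542) together with either Sigma70_r4
  (PF04545) or Sigma70_r4_2 (PF08281).  Group 1/2 additionally
  requires both Sigma70_r1_2 (PF00140) and Sigma70_r3 (PF04539);
  group 3 has Sigma70_r3 without Sigma70_r1_2; everything else is
  group 4 (the extracytoplasmic-function subfamily).  Sigma-54-family
  factors carry any of PF00309/PF04963/PF04552; a protein matching
  both families is called sigma-70 and flagged as a conflict (no
  sigma-54 factor has been reported in streptomycetes).

* transcription factors: matched against an external table of
  P2TF-style domain architectures (required / forbidden domain sets
  with priorities); proteins already called sigma factors are
  excluded.  A small built-in rule table covers five common families
  for testing; the full architecture catalogue is user-supplied.

* chaplins: any hit of the chaplin domain PF03777 (hits are expected
  to be pre-filtered at the Pfam threshold of 1e-1).

* PPTases: at least one 4'-phosphopantetheinyl transferase domain
  PF01648 at independent E < 1e-3 (this rule applies its own, stricter
  threshold to raw hits).  Sfp-type PPTases carry a second transferase
  domain, operationalised as >= 2 envelope-non-overlapping passing
  hits; a single passing hit is AcpS-type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError
from .io import iter_tsv_rows

logger = logging.getLogger(__name__)

SIGMA70_R2 = "PF04542"
SIGMA70_R4 = "PF04545"
SIGMA70_R4_2 = "PF08281"
SIGMA70_R1_2 = "PF00140"
SIGMA70_R3 = "PF04539"
SIGMA54_DOMAINS = frozenset({"PF00309", "PF04963", "PF04552"})
CHAPLIN_DOMAIN = "PF03777"
PPTASE_DOMAIN = "PF01648"
PPTASE_EVALUE = 1e-3

GROUP_1_OR_2 = "group_1_or_2"
GROUP_3 = "group_3"
GROUP_4 = "group_4"


@dataclass(frozen=True)
class DomainHit:
    """One domain hit with its independent E-value and envelope."""

    protein_id: str
    accession: str
    name: str
    ievalue: float
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.ievalue < 0:
            raise ValueError(f"negative E-value for {self.protein_id}/{self.accession}")
        if self.start > self.end:
            raise ValueError(
                f"start > end in hit {self.protein_id}/{self.accession}"
            )

    def overlaps(self, other: "DomainHit") -> bool:
        """True when the envelopes share at least one residue."""
        return self.start <= other.end and other.start <= self.end


def group_hits_by_protein(hits: Iterable[DomainHit]) -> dict[str, list[DomainHit]]:
    grouped: dict[str, list[DomainHit]] = {}
    for hit in hits:
        grouped.setdefault(hit.protein_id, []).append(hit)
    return grouped


@dataclass(frozen=True)
class SigmaFactorCall:
    protein_id: str
    family: str  # "sigma70" or "sigma54"
    group: str | None = None  # sigma70 only

    def __post_init__(self) -> None:
        if (self.group is not None) != (self.family == "sigma70"):
            raise ValueError("group is set iff the family is sigma70")


def classify_sigma(
    hits_by_protein: Mapping[str, Sequence[DomainHit]],
) -> dict[str, SigmaFactorCall]:
    """Call sigma factors and their groups from per-protein domain sets.

    Hits are assumed pre-filtered at the Pfam independent-E-value
    threshold (1e-1).  Returns calls keyed by protein id; proteins
    matching neither family are absent from the result.
    """
    calls: dict[str, SigmaFactorCall] = {}
    for protein_id in sorted(hits_by_protein):
        domains = {h.accession for h in hits_by_protein[protein_id]}
        is_sigma70 = SIGMA70_R2 in domains and (
            SIGMA70_R4 in domains or SIGMA70_R4_2 in domains
        )
        is_sigma54 = bool(domains & SIGMA54_DOMAINS)
        if is_sigma70:
            if is_sigma54:
                logger.warning(
                    "protein %s matches both sigma70 and sigma54 rules; "
                    "calling sigma70",
                    protein_id,
                )
            if SIGMA70_R1_2 in domains and SIGMA70_R3 in domains:
                group = GROUP_1_OR_2
            elif SIGMA70_R3 in domains:
                group = GROUP_3
            else:
                group = GROUP_4
            calls[protein_id] = SigmaFactorCall(protein_id, "sigma70", group)
        elif is_sigma54:
            calls[protein_id] = SigmaFactorCall(protein_id, "sigma54")
    return calls


@dataclass(frozen=True)
class ArchitectureRule:
    """A P2TF-style transcription-factor domain architecture."""

    rule_id: str
    family: str
    required: frozenset[str]
    forbidden: frozenset[str] = frozenset()
    priority: int = 100

    def __post_init__(self) -> None:
        if not self.required:
            raise ConfigurationError(f"rule {self.rule_id!r} has no required domains")
        if self.required & self.forbidden:
            raise ConfigurationError(
                f"rule {self.rule_id!r}: required and forbidden sets overlap"
            )

    def matches(self, domains: frozenset[str]) -> bool:
        return self.required <= domains and not (self.forbidden & domains)


def load_tf_rules(path: str | Path | None = None) -> list[ArchitectureRule]:
    """Load an architecture rule table (TSV).

    Columns: rule_id, family, required (comma-separated accessions),
    forbidden (comma-separated, may be empty), priority (smaller wins).
    Without a path the small built-in five-family table is returned.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "tf_architectures.tsv"
    rules: list[ArchitectureRule] = []
    for lineno, fields in iter_tsv_rows(path):
        if lineno == 1 and fields[0] == "rule_id":
            continue
        if len(fields) != 5:
            raise ConfigurationError(f"{path} line {lineno}: expected 5 columns")
        rule_id, family, required, forbidden, priority = fields
        rules.append(
            ArchitectureRule(
                rule_id=rule_id,
                family=family,
                required=frozenset(d for d in required.split(",") if d),
                forbidden=frozenset(d for d in forbidden.split(",") if d),
                priority=int(priority),
            )
        )
    if not rules:
        raise ConfigurationError(f"empty transcription-factor rule table: {path}")
    return rules


def classify_tf(
    hits_by_protein: Mapping[str, Sequence[DomainHit]],
    rules: Sequence[ArchitectureRule],
    sigma_calls: Mapping[str, SigmaFactorCall] | None = None,
) -> dict[str, str]:
    """Assign transcription-factor families by domain architecture.

    The matching rule with the smallest priority wins (ties by rule
    order); proteins already called sigma factors are excluded.
    Returns protein id -> family name.
    """
    if not rules:
        raise ConfigurationError("empty transcription-factor rule table")
    ordered = sorted(enumerate(rules), key=lambda ir: (ir[1].priority, ir[0]))
    sigma = sigma_calls or {}
    out: dict[str, str] = {}
    for protein_id in sorted(hits_by_protein):
        if protein_id in sigma:
            continue
        domains = frozenset(h.accession for h in hits_by_protein[protein_id])
        matching = [rule for _, rule in ordered if rule.matches(domains)]
        if not matching:
            continue
        if len(matching) > 1:
            logger.info(
                "protein %s matches %d architecture rules; keeping %s",
                protein_id,
                len(matching),
                matching[0].family,
            )
        out[protein_id] = matching[0].family
    return out


def identify_chaplins(
    hits_by_protein: Mapping[str, Sequence[DomainHit]],
) -> set[str]:
    """Proteins with at least one chaplin-domain (PF03777) hit."""
    return {
        pid
        for pid, hits in hits_by_protein.items()
        if any(h.accession == CHAPLIN_DOMAIN for h in hits)
    }


@dataclass(frozen=True)
class PPTaseCall:
    protein_id: str
    pptase_type: str  # "AcpS" or "Sfp"
    n_domains: int


def _max_non_overlapping(hits: list[DomainHit]) -> int:
    """Size of a largest set of mutually non-overlapping envelopes.

    Greedy interval scheduling on end coordinates, which is optimal for
    this objective.
    """
    count, last_end = 0, 0
    for hit in sorted(hits, key=lambda h: (h.end, h.start)):
        if hit.start > last_end:
            count += 1
            last_end = hit.end
    return count


def identify_pptases(
    hits_by_protein: Mapping[str, Sequence[DomainHit]],
    evalue_threshold: float = PPTASE_EVALUE,
) -> dict[str, PPTaseCall]:
    """Call PPTases and type them as AcpS (one domain) or Sfp (two).

    Applies its own strict E < 1e-3 threshold to PF01648 hits, so raw
    (unfiltered) hits should be passed in.  Sfp-type means at least two
    non-overlapping passing transferase domains (overlap = any shared
    residue).
    """
    calls: dict[str, PPTaseCall] = {}
    for protein_id in sorted(hits_by_protein):
        passing = [
            h
            for h in hits_by_protein[protein_id]
            if h.accession == PPTASE_DOMAIN and h.ievalue < evalue_threshold
        ]
        if not passing:
            continue
        n_domains = _max_non_overlapping(passing)
        calls[protein_id] = PPTaseCall(
            protein_id=protein_id,
            pptase_type="Sfp" if n_domains >= 2 else "AcpS",
            n_domains=n_domains,
        )
    return calls
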