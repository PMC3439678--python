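"""Pipeline thresholds.

All cut-offs used along the pipeline live in one dataclass so that a run is
fully described by its inputs plus one :class:`Thresholds` instance.  The
defaults are the similarity-network and validation settings the annotation
resource operates with: edges require >=40% identity over >=90% coverage,
structural templates must cover >=70% of the mature reference sequence, and
ontology/domain terms are inherited only below a Bonferroni-corrected
p-value of 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml


@dataclass(frozen=True)
class Thresholds:
    """Cut-offs applied along the pipeline.

    Parameters
    ----------
    min_identity : float
        Minimum pairwise sequence identity (percent) for a similarity edge.
    min_coverage : float
        Minimum alignment coverage of the longer sequence (percent) for a
        similarity edge.
    template_min_coverage : float
        Minimum fraction (0-1) of the mature reference sequence resolved in
        a structural template for it to be accepted.
    enrichment_alpha : float
        Significance threshold on the Bonferroni-corrected hypergeometric
        p-value for term inheritance.
    similar_cutoff : int
        BLOSUM62 score strictly above which a non-identical substitution is
        classed "similar".
    metal_code : str
        Hetero-group code of the metal of interest.
    water_codes : frozenset[str]
        Residue names treated as water.
    max_contact_distance : float | None
        Optional sanity cut (angstrom) on LINK distances; ``None`` disables
        it (the depositor's LINK annotation is trusted by default).
    """

    min_identity: float = 40.0
    min_coverage: float = 90.0
    template_min_coverage: float = 0.70
    enrichment_alpha: float = 0.01
    similar_cutoff: int = 0
    metal_code: str = "MG"
    water_codes: frozenset = frozenset({"HOH", "DOD", "WAT"})
    max_contact_distance: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_identity <= 100.0):
            raise ValueError("min_identity must be a percentage in [0, 100]")
        if not (0.0 <= self.min_coverage <= 100.0):
            raise ValueError("min_coverage must be a percentage in [0, 100]")
        if not (0.0 <= self.template_min_coverage <= 1.0):
            raise ValueError("template_min_coverage must be a fraction in [0, 1]")
        if not (0.0 < self.enrichment_alpha <= 1.0):
            raise ValueError("enrichment_alpha must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "Thresholds":
        """Load thresholds from a YAML mapping; absent keys keep defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        if "water_codes" in raw:
            raw["water_codes"] = frozenset(raw["water_codes"])
        return cls(**raw)


DEFAULT_THRESHOLDS = Thresholds()
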