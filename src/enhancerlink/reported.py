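"""Published counts from the macrophage RXR enhancer-network study.

These are inputs, not results: the arithmetic identities among them
(active-enhancer fraction, assigned-region total, domain residency,
validated-region total) are recomputed from the raw counts wherever the
package reports them.
"""

from __future__ import annotations

#: signal-factor (RXR) binding regions overlapping a divergent site
GRO_POSITIVE_SITES = 2781
#: signal-factor binding regions without divergent-transcription overlap
GRO_NEGATIVE_SITES = 2425
#: regulatory regions assigned to regulated genes, by class
ENHANCERS = 387
SILENCERS = 27
#: genes with at least one assigned regulatory region
REGULATED_GENES = 252
#: regulated genes residing, with all their enhancers, in merged domains
GENES_IN_DOMAINS = 203
#: CTCF/RAD21 co-peak boundaries and the functional domains paired from them
CO_PEAK_BOUNDARIES = 12_660
FUNCTIONAL_DOMAINS = 10_204
MEDIAN_DOMAIN_KB = 81.15
MEAN_DOMAIN_KB = 149.98
#: divergent transcription sites genome-wide (>0.2 RPKM)
DIVERGENT_SITES = 51_657
#: changing divergent sites also bound by the signal factor
CHANGING_RXR_SITES = 718
#: reporter-validated regulatory regions: distant (>10 kb) + proximal
VALIDATED_DISTANT = 30
VALIDATED_PROXIMAL = 15


def active_enhancer_fraction_pct() -> float:
    """Assigned enhancers as a percentage of all signal-factor peaks."""
    return 100.0 * ENHANCERS / (GRO_POSITIVE_SITES + GRO_NEGATIVE_SITES)


def assigned_regions() -> int:
    """Total regulatory regions assigned to genes (enhancers + silencers)."""
    return ENHANCERS + SILENCERS


def domain_residency_pct() -> float:
    """Percentage of regulated genes confined to merged domains."""
    return 100.0 * GENES_IN_DOMAINS / REGULATED_GENES


def validated_regions() -> int:
    """Reporter-validated regulatory regions (distant + proximal)."""
    return VALIDATED_DISTANT + VALIDATED_PROXIMAL
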