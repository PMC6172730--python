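"""Published constants of the fly targeting-efficacy model.

These are reported quantities of the trained genome-scale model that the
package treats as inputs: the bootstrap selection frequency of each of
the 17 candidate features, the per-site-type estimates of 3' UTR sites
conserved above background (at a branch-length cutoff of 1.0), and the
normal distributions of preferentially conserved UTR site counts that
drive the conserved-gene-count simulation.  The score caps live with the
model in :mod:`flyseed.repression_model`.
"""

from __future__ import annotations

from .site_finder import SiteType

#: Fraction of bootstrap samples selecting each feature during stepwise
#: regression on the transfection compendium.
FEATURE_SELECTION_FREQUENCY = {
    "site_type": 1.00,
    "site9": 0.02,
    "site10": 0.00,
    "local_AU": 0.51,
    "3P_score": 0.04,
    "3P_energy": 0.94,
    "SA": 0.92,
    "PCT": 1.00,
    "len_5UTR": 0.30,
    "len_ORF": 1.00,
    "len_3UTR": 1.00,
    "AU_5UTR": 0.17,
    "AU_ORF": 0.37,
    "AU_3UTR": 0.56,
    "dist_stop": 0.04,
    "min_dist": 0.55,
    "other_sites": 1.00,
}

#: Threshold on the selection frequency defining the robust feature set.
ROBUST_FREQUENCY_THRESHOLD = 0.90


def robust_feature_set(
    frequencies: dict[str, float] | None = None,
    threshold: float = ROBUST_FREQUENCY_THRESHOLD,
) -> list[str]:
    """Features selected in at least *threshold* of bootstrap samples."""
    freqs = FEATURE_SELECTION_FREQUENCY if frequencies is None else frequencies
    return [name for name, f in freqs.items() if f >= threshold]


#: Estimated 3' UTR sites conserved above background per site type, at a
#: branch-length cutoff of 1.0 (site types whose lower 5% confidence
#: limit exceeded zero).
CONSERVED_UTR3_SITES_ABOVE_BACKGROUND = {
    SiteType.EIGHTMER: 2738,
    SiteType.SEVENMER_M8: 2837,
    SiteType.SEVENMER_A1: 4062,
    SiteType.SIXMER: 2128,
    SiteType.OFFSET_SIXMER: 520,
}

#: Estimated 5' UTR sites conserved above background per site type.
CONSERVED_UTR5_SITES_ABOVE_BACKGROUND = {
    SiteType.EIGHTMER: 350,
    SiteType.SEVENMER_M8: 165,
    SiteType.SEVENMER_A1: 325,
}

#: Normal distributions (mean, SD) of the total preferentially conserved
#: site counts used by the conserved-gene-count simulation.
CONSERVED_SITE_COUNT_DISTRIBUTIONS = {
    "UTR5": (840.0, 40.0),
    "UTR3": (12285.0, 214.0),
}
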