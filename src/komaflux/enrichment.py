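"""Bulk biomass 13C accounting for EA-IRMS interpretation.

After growth on a positionally labeled tracer, the expected total 13C content
of biomass is modeled as a two-pool mixture: carbon present before the
labeling period stays at its initial enrichment (natural abundance by
default), carbon fixed during growth carries the mean per-carbon enrichment
of the tracer.  For an x-fold biomass increase, the newly synthesized carbon
fraction is f = (x - 1) / x, giving

    expected 13C [%] = 100 * (f * e_tracer + (1 - f) * e_initial)

The mixing model deliberately ignores respiratory fractionation and carbon
turnover (see the methods note for the discrepancy this produces against
measured bulk enrichments).
"""

from __future__ import annotations

import dataclasses

from .correction import NATURAL_13C


@dataclasses.dataclass
class EnrichmentModel:
    fold_increase: float
    tracer_mean_enrichment: float
    initial_enrichment: float = NATURAL_13C

    def __post_init__(self) -> None:
        if self.fold_increase < 1.0:
            raise ValueError("fold_increase must be >= 1")
        for name in ("tracer_mean_enrichment", "initial_enrichment"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1]")


def natural_13c_fraction(decimals: int | None = 1) -> float:
    """Packaged natural 13C abundance as percent of carbon (1.07%; 1.1% at one decimal)."""
    pct = 100.0 * NATURAL_13C
    return round(pct, decimals) if decimals is not None else pct


def tracer_mean_enrichment(n_carbons: int, labeled_positions: dict[int, float],
                           natural: float = NATURAL_13C) -> float:
    """Mean per-carbon 13C enrichment of a tracer.

    ``labeled_positions`` maps 1-based carbon positions to enrichment
    fractions; unlisted positions sit at natural abundance.  For 1-13C xylose
    at purity p this is (p + 4 * 0.0107) / 5.
    """
    e = [labeled_positions.get(i, natural) for i in range(1, n_carbons + 1)]
    return sum(e) / n_carbons


def expected_total_13c(model: EnrichmentModel) -> float:
    """Expected bulk biomass 13C content in percent under the two-pool model."""
    f_new = (model.fold_increase - 1.0) / model.fold_increase
    frac = f_new * model.tracer_mean_enrichment + (1.0 - f_new) * model.initial_enrichment
    return 100.0 * frac
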