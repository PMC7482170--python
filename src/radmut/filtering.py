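"""Allele-frequency, cross-sample and zygosity filtering of candidate calls.

The rules mirror a standard M2 resequencing screen for induced mutations:

* calls with mutant-read allele frequency (AF) <= 25% are discarded;
* a site called in more than two independent samples is discarded as a
  systematic artifact (mapping error, paralogy);
* a surviving call is heterozygous when 25% < AF < 80%, homozygous when
  AF >= 80%, and in either case every *other* sample must show AF < 5%
  at that site — otherwise the call is rejected as cross-sample signal.

Every candidate ends in exactly one of five bins: retained-homozygous,
retained-heterozygous, excluded-low-AF, excluded-shared, or
rejected-other-sample-signal. ``FilterResult`` keeps all five so stage
counts are conserved.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace as dc_replace

from .variants import CandidateCall, FilteredCall


@dataclass(frozen=True)
class FilterConfig:
    af_exclusion_max: float = 0.25   # AF <= this is excluded
    het_hom_boundary: float = 0.80   # AF >= this is homozygous
    other_sample_max: float = 0.05   # other samples must be below this
    shared_site_max_samples: int = 2  # site in more than this many samples is dropped


@dataclass
class FilterResult:
    retained: list[FilteredCall] = field(default_factory=list)
    excluded_low_af: list[CandidateCall] = field(default_factory=list)
    excluded_shared: list[CandidateCall] = field(default_factory=list)
    rejected_other_sample: list[CandidateCall] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return (
            len(self.retained)
            + len(self.excluded_low_af)
            + len(self.excluded_shared)
            + len(self.rejected_other_sample)
        )

    def counts(self) -> dict[str, int]:
        return {
            "retained": len(self.retained),
            "excluded_low_af": len(self.excluded_low_af),
            "excluded_shared": len(self.excluded_shared),
            "rejected_other_sample": len(self.rejected_other_sample),
        }


def exclude_low_af(
    calls: list[CandidateCall], af_exclusion_max: float = 0.25
) -> tuple[list[CandidateCall], list[CandidateCall]]:
    """Split calls into (retained, excluded); retained iff AF > threshold."""
    kept = [c for c in calls if c.allele_frequency > af_exclusion_max]
    dropped = [c for c in calls if c.allele_frequency <= af_exclusion_max]
    return kept, dropped


def exclude_shared_sites(
    calls: list[CandidateCall], max_samples: int = 2
) -> tuple[list[CandidateCall], list[CandidateCall]]:
    """Drop every call at any site seen in more than ``max_samples`` samples."""
    samples_at_site: dict[tuple, set[str]] = defaultdict(set)
    for c in calls:
        samples_at_site[c.site_key].add(c.sample_id)
    kept, dropped = [], []
    for c in calls:
        (dropped if len(samples_at_site[c.site_key]) > max_samples else kept).append(c)
    return kept, dropped


def assign_zygosity(
    call: CandidateCall,
    af_in_other_samples: list[float],
    config: FilterConfig = FilterConfig(),
) -> FilteredCall | None:
    """Return a zygosity-labelled call, or None when rejected.

    Requires AF above the low-AF exclusion threshold and AF below
    ``other_sample_max`` in every other sample.
    """
    af = call.allele_frequency
    if af <= config.af_exclusion_max:
        return None
    if any(a >= config.other_sample_max for a in af_in_other_samples):
        return None
    zyg = "homozygous" if af >= config.het_hom_boundary else "heterozygous"
    return FilteredCall(**{**call.__dict__, "zygosity": zyg})


def filter_calls(
    calls: list[CandidateCall], config: FilterConfig = FilterConfig()
) -> FilterResult:
    """Run the full filter cascade over a multi-sample candidate set.

    The cross-sample AF check for zygosity uses the *candidate* AFs: a
    site's AF in another sample is the AF reported there, or 0 when that
    sample has no call at the site.
    """
    result = FilterResult()

    kept, low = exclude_low_af(calls, config.af_exclusion_max)
    result.excluded_low_af.extend(low)

    kept, shared = exclude_shared_sites(kept, config.shared_site_max_samples)
    result.excluded_shared.extend(shared)

    af_by_site: dict[tuple, dict[str, float]] = defaultdict(dict)
    for c in calls:  # all candidates, incl. low-AF, inform the cross-sample check
        prev = af_by_site[c.site_key].get(c.sample_id, 0.0)
        af_by_site[c.site_key][c.sample_id] = max(prev, c.allele_frequency)

    for c in kept:
        others = [
            af
            for sample, af in af_by_site[c.site_key].items()
            if sample != c.sample_id
        ]
        fc = assign_zygosity(c, others, config)
        if fc is None:
            result.rejected_other_sample.append(c)
        else:
            result.retained.append(fc)
    return result
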