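"""Depth-aware tumor mutational burden (TMB) from targeted-panel calls.

A mutation at observed VAF v is detectable at a site only if that site's
depth can yield at least 8 mutant reads, i.e. depth >= ceil(8/v).  Each
detected mutation m therefore represents 1/B_m mutations per panel site,
where B_m is the number of panel sites at or above its required depth.
TMB per megabase is

    TMB = 1e6 * (1/B_1 + ... + 1/B_m).

Under uniform adequate coverage this reduces to mutation count / footprint
* 1e6; under nonuniform coverage low-VAF mutations are up-weighted because
fewer sites could have revealed them.  Mutations whose required depth
exceeds the deepest bin (B_m = 0) cannot be extrapolated and are excluded
with a report entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .records import DepthProfile, VariantObservation

MIN_MUTANT_READS = 8


@dataclass(frozen=True)
class TMBContribution:
    variant_key: tuple
    vaf: float
    required_depth: int
    detectable_sites: int  # B_m
    weight: float  # 1/B_m


@dataclass
class TMBEstimate:
    tmb_per_mb: float
    contributions: list = field(default_factory=list)
    excluded: list = field(default_factory=list)  # variant keys with B_m = 0


def required_depth(vaf: float) -> int:
    """Minimum depth for >=8 expected mutant reads at allele fraction vaf."""
    if vaf <= 0 or vaf > 1:
        raise ValueError("vaf must be in (0,1]")
    # guard against float quotients landing epsilon above an integer
    return int(math.ceil(MIN_MUTANT_READS / vaf - 1e-9))


def detectability_count(profile: DepthProfile, vaf: float) -> int:
    """B_m: number of profile sites deep enough to detect a VAF-v mutation."""
    return profile.sites_at_least(required_depth(vaf))


def tmb_estimate(
    mutations: Sequence[VariantObservation],
    profile: DepthProfile,
    include_silent: bool = False,
) -> TMBEstimate:
    """Extrapolate TMB from kept mutations and the sample's depth profile.

    Counts protein-altering calls by default; ``include_silent`` adds silent
    calls (for WES-style inputs).
    """
    if profile.footprint == 0:
        raise ValueError("empty depth profile")
    est = TMBEstimate(0.0)
    total = 0.0
    for m in mutations:
        if m.effect == "silent" and not include_silent:
            continue
        req = required_depth(m.vaf)
        b = profile.sites_at_least(req)
        if b == 0:
            est.excluded.append(m.key)
            continue
        w = 1.0 / b
        total += w
        est.contributions.append(TMBContribution(m.key, m.vaf, req, b, w))
    est.tmb_per_mb = 1e6 * total
    return est
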