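"""Stimulus-selectivity classification and density / Venn / fold summaries.

A knob tested against two stimuli falls into exactly one of four classes:
responsive only to the first (``A_only``), only to the second (``B_only``),
to both (``both``), or to neither (``none``).  Class sizes are reported as
densities — percent of the *estimated total knobs* at a site — averaged
across recording sites, and as Venn shares — percent of all responsive
knobs.  Because site-mean densities and pooled responder counts give
slightly different shares, both conventions are computed and labelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._util import DataError, round_half_away, sem
from .knobs import SiteGeometry

CLASSES = ("A_only", "B_only", "both")
ALL_CLASSES = CLASSES + ("none",)


def classify_knob(flag_a: bool, flag_b: bool) -> str:
    """Map the two per-stimulus responder flags to a selectivity class."""
    if flag_a and flag_b:
        return "both"
    if flag_a:
        return "A_only"
    if flag_b:
        return "B_only"
    return "none"


@dataclass
class ResponderProfile:
    """Per-knob responsiveness flags and derived selectivity class."""

    knob_id: str
    responds_a: bool
    responds_b: bool

    @property
    def selectivity_class(self) -> str:
        return classify_knob(self.responds_a, self.responds_b)


@dataclass
class SiteSummary:
    """Per-class counts and densities (% of estimated total knobs) at a site."""

    site_id: str
    estimated_total_knobs: int
    counts: dict[str, int]
    densities_pct: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.estimated_total_knobs <= 0:
            raise DataError(f"site {self.site_id}: estimated total knobs must be > 0")
        self.densities_pct = {
            c: 100.0 * self.counts.get(c, 0) / self.estimated_total_knobs for c in CLASSES
        }

    @property
    def n_responders(self) -> int:
        return sum(self.counts.get(c, 0) for c in CLASSES)


def site_summary(
    profiles: Sequence[ResponderProfile], geometry: SiteGeometry
) -> SiteSummary:
    """Count selectivity classes and express them as % of total knobs."""
    total = geometry.estimated_total_knobs
    if total < len(profiles):
        raise DataError(
            f"site {geometry.site_id}: estimated total knobs ({total}) below "
            f"profiled knob count ({len(profiles)})"
        )
    counts = {c: 0 for c in ALL_CLASSES}
    for p in profiles:
        counts[p.selectivity_class] += 1
    return SiteSummary(geometry.site_id, total, counts)


def profiles_from_flags(df: pd.DataFrame, stim_a: str, stim_b: str) -> list[ResponderProfile]:
    """Build profiles from an ``analyze_dataset`` flag table."""
    cols = (f"responds_{stim_a}", f"responds_{stim_b}")
    for c in cols:
        if c not in df.columns:
            raise DataError(f"flag table missing column {c!r}")
    return [
        ResponderProfile(str(r.knob_id), bool(getattr(r, cols[0])), bool(getattr(r, cols[1])))
        for r in df.itertuples()
    ]


@dataclass
class GroupSummary:
    """Across-site class summaries for one experimental group."""

    n_sites: int
    mean_density_pct: dict[str, float]
    sem_density_pct: dict[str, Optional[float]]
    pooled_counts: dict[str, int]
    pooled_responders: int
    venn_shares_from_counts: dict[str, float]
    venn_shares_from_densities: dict[str, float]

    def to_report(self) -> dict:
        """Machine-readable report carrying both Venn conventions, labelled."""
        return {
            "n_sites": self.n_sites,
            "class_density_pct": {
                c: {"mean": self.mean_density_pct[c], "sem": self.sem_density_pct[c]}
                for c in CLASSES
            },
            "pooled_responder_count": self.pooled_responders,
            "venn_shares_pct": {
                "convention": {
                    "from_pooled_counts": "class count / summed responder count across sites",
                    "from_mean_densities": "mean site density / summed mean site densities",
                },
                "from_pooled_counts": self.venn_shares_from_counts,
                "from_mean_densities": self.venn_shares_from_densities,
            },
        }


def venn_shares(class_sizes: dict[str, float]) -> dict[str, float]:
    """Each responsive class as % of all responsive knobs (sums to 100)."""
    total = sum(class_sizes.get(c, 0.0) for c in CLASSES)
    if total <= 0:
        raise DataError("no responsive knobs: Venn shares undefined")
    return {c: 100.0 * class_sizes.get(c, 0.0) / total for c in CLASSES}


def group_summary(sites: Sequence[SiteSummary]) -> GroupSummary:
    """Mean +/- SEM densities across sites plus both Venn conventions."""
    if len(sites) < 1:
        raise ValueError("at least one site is required")
    mean_d = {c: float(np.mean([s.densities_pct[c] for s in sites])) for c in CLASSES}
    sem_d = {c: sem([s.densities_pct[c] for s in sites]) for c in CLASSES}
    pooled = {c: int(sum(s.counts.get(c, 0) for s in sites)) for c in CLASSES}
    n_resp = sum(pooled.values())
    return GroupSummary(
        n_sites=len(sites),
        mean_density_pct=mean_d,
        sem_density_pct=sem_d,
        pooled_counts=pooled,
        pooled_responders=n_resp,
        venn_shares_from_counts=venn_shares({c: float(v) for c, v in pooled.items()}),
        venn_shares_from_densities=venn_shares(mean_d),
    )


def fold_change(reference: float, comparison: float) -> tuple[float, bool]:
    """Fold ratio reference/comparison; flag True marks an undefined/infinite fold."""
    if reference < 0 or comparison < 0:
        raise ValueError("densities must be non-negative")
    if comparison == 0:
        if reference == 0:
            return math.nan, True
        return math.inf, True
    return reference / comparison, False


def activated_share(class_densities: dict[str, float], target: str) -> float:
    """Percent of all activated knobs responding to ``target`` (exclusive + shared).

    ``target`` is ``"A"`` or ``"B"``; the share counts the target-only class
    plus the non-discriminating ``both`` class.
    """
    shares = venn_shares(class_densities)
    return shares[f"{target}_only"] + shares["both"]


def exclusive_share(class_densities: dict[str, float], target: str) -> float:
    """Percent of all activated knobs responding *only* to ``target``."""
    return venn_shares(class_densities)[f"{target}_only"]


def total_response_ratio(class_densities: dict[str, float], target: str) -> float:
    """Ratio of total target responders to total other-stimulus responders.

    Total responders to a stimulus include the shared class, so for target A
    this is (A_only + both) / (B_only + both).
    """
    other = "B" if target == "A" else "A"
    num = class_densities.get(f"{target}_only", 0.0) + class_densities.get("both", 0.0)
    den = class_densities.get(f"{other}_only", 0.0) + class_densities.get("both", 0.0)
    if den <= 0:
        raise DataError("other-stimulus response total is zero: ratio undefined")
    return num / den


def headline(value: float, ndigits: int = 0) -> float:
    """Round a headline share/fold to printed precision, half away from zero."""
    return round_half_away(value, ndigits)
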