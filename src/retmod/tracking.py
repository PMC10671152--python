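"""Peak tracking across design runs via the three-mixture spiking scheme.

Instead of relying on spectra, analyte identities are established by
injecting, at every design condition, several artificial mixtures that each
contain a known subset of the analytes.  A peak observed in the full mixture
is matched (by retention time, within a replicate-injection window) against
the partial-mixture injections, giving a presence/absence *signature* that
narrows it down to the analytes sharing that signature.  Remaining ties are
broken by comparing relative peak areas with the nominal concentrations, and
optionally by a user-supplied expected elution order.  Peaks that cannot be
resolved are flagged ambiguous — never silently guessed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import IncompleteEvidenceError, ValidationError

__all__ = [
    "MixtureScheme",
    "ObservedPeak",
    "PeakAssignment",
    "membership_signature",
    "assign_peaks",
    "assignments_to_rows",
]

#: Retention-time window (min) for matching replicate injections of the same
#: condition across mixtures.
DEFAULT_RT_WINDOW = 0.1

#: Two candidate areas whose ratio is within this fraction are treated as
#: indistinguishable.
DEFAULT_AREA_TOLERANCE = 0.10


@dataclass(frozen=True)
class MixtureScheme:
    """mixture_id -> {analyte_id: nominal concentration (µg/mL)}.

    The mixtures must jointly cover every analyte and at least one mixture
    (the *full* mixture) must contain all of them.
    """

    mixtures: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        if not self.mixtures:
            raise ValidationError("a mixture scheme needs at least one mixture")
        all_analytes = set().union(*(m.keys() for m in self.mixtures.values()))
        if not any(set(m) == all_analytes for m in self.mixtures.values()):
            raise ValidationError(
                "at least one mixture must contain every analyte (the full mixture)"
            )
        for mid, comp in self.mixtures.items():
            for a, c in comp.items():
                if c <= 0:
                    raise ValidationError(
                        f"non-positive concentration for {a!r} in {mid!r}"
                    )

    @property
    def mixture_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.mixtures))

    @property
    def analytes(self) -> tuple[str, ...]:
        return tuple(sorted(set().union(*(m.keys() for m in self.mixtures.values()))))

    @property
    def full_mixture_id(self) -> str:
        alls = set(self.analytes)
        for mid in self.mixture_ids:
            if set(self.mixtures[mid]) == alls:
                return mid
        raise AssertionError("unreachable: validated in __post_init__")


@dataclass(frozen=True)
class ObservedPeak:
    """One detected/integrated peak from one mixture injection."""

    run_id: str
    mixture_id: str
    rt_min: float
    area: float

    def __post_init__(self) -> None:
        if self.rt_min <= 0:
            raise ValidationError("retention time must be positive")
        if self.area <= 0:
            raise ValidationError("area must be positive")


@dataclass(frozen=True)
class PeakAssignment:
    """Label (or ambiguity flag) for one full-mixture peak."""

    rt_min: float
    area: float
    analyte: str | None
    ambiguous: bool
    candidates: tuple[str, ...]
    reason: str


def membership_signature(analyte_id: str, scheme: MixtureScheme) -> tuple[bool, ...]:
    """Presence/absence of the analyte across mixtures (sorted mixture ids)."""
    if analyte_id not in scheme.analytes:
        raise ValidationError(f"unknown analyte {analyte_id!r}")
    return tuple(analyte_id in scheme.mixtures[m] for m in scheme.mixture_ids)


_FAR = 1e9


def _observed_signatures(
    full_peaks: list[ObservedPeak],
    peaks_by_mixture: dict[str, list[ObservedPeak]],
    mixture_ids: tuple[str, ...],
    full_id: str,
    window: float,
) -> list[tuple[bool, ...]]:
    """Presence/absence of every full-mixture peak across the partial mixtures.

    Matching is one-to-one per mixture (minimum total |delta rt|, pairs
    farther than the window forbidden): a partial-mixture peak can vouch for
    at most one full-mixture peak, so two nearly co-eluted full-mixture
    peaks cannot both claim the same replicate peak.
    """
    present = {m: [False] * len(full_peaks) for m in mixture_ids}
    for m in mixture_ids:
        if m == full_id:
            present[m] = [True] * len(full_peaks)
            continue
        others = peaks_by_mixture.get(m, [])
        if not others:
            continue
        cost = np.full((len(full_peaks), len(others)), _FAR)
        for i, p in enumerate(full_peaks):
            for j, q in enumerate(others):
                d = abs(p.rt_min - q.rt_min)
                if d <= window:
                    cost[i, j] = d
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if cost[i, j] < _FAR:
                present[m][i] = True
    return [
        tuple(present[m][i] for m in mixture_ids) for i in range(len(full_peaks))
    ]


def assign_peaks(
    peaks: list[ObservedPeak],
    scheme: MixtureScheme,
    rt_window: float = DEFAULT_RT_WINDOW,
    area_tolerance: float = DEFAULT_AREA_TOLERANCE,
    reference_order: list[str] | None = None,
) -> list[PeakAssignment]:
    """Label the full-mixture peaks of one design condition.

    Evidence is combined in a fixed order: mixture signature first, then
    relative areas against nominal concentrations (tolerant to modest
    response-factor differences), then the optional expected elution order.
    The result is order-independent in the input peak list and is a partial
    injection: no label is used twice, flagged peaks carry no label.
    """
    if not peaks:
        raise ValidationError("no peaks supplied")
    by_mix: dict[str, list[ObservedPeak]] = {}
    for p in sorted(peaks, key=lambda q: (q.rt_min, q.area)):
        by_mix.setdefault(p.mixture_id, []).append(p)
    missing = set(scheme.mixture_ids) - set(by_mix)
    if missing:
        raise IncompleteEvidenceError(
            f"missing mixture injections: {sorted(missing)}"
        )
    full_id = scheme.full_mixture_id
    full_peaks = by_mix[full_id]
    mixture_ids = scheme.mixture_ids
    full_conc = scheme.mixtures[full_id]

    sigs = _observed_signatures(full_peaks, by_mix, mixture_ids, full_id, rt_window)
    groups: dict[tuple[bool, ...], list[ObservedPeak]] = {}
    for p, sig in zip(full_peaks, sigs):
        groups.setdefault(sig, []).append(p)

    sig_of = {a: membership_signature(a, scheme) for a in scheme.analytes}
    out: list[PeakAssignment] = []
    for sig, group in sorted(groups.items()):
        candidates = tuple(sorted(a for a, s in sig_of.items() if s == sig))
        group = sorted(group, key=lambda p: (p.rt_min, p.area))
        if not candidates:
            out.extend(
                PeakAssignment(p.rt_min, p.area, None, True, (), "no-matching-signature")
                for p in group
            )
            continue
        if len(group) != len(candidates):
            out.extend(
                PeakAssignment(
                    p.rt_min, p.area, None, True, candidates,
                    f"count-mismatch ({len(group)} peaks, {len(candidates)} candidates)",
                )
                for p in group
            )
            continue
        if len(candidates) == 1:
            p = group[0]
            out.append(
                PeakAssignment(p.rt_min, p.area, candidates[0], False, candidates,
                               "unique-signature")
            )
            continue
        out.extend(
            _assign_within_group(group, candidates, full_conc, area_tolerance,
                                 reference_order)
        )
    out.sort(key=lambda a: a.rt_min)
    return out


def _assign_within_group(
    group: list[ObservedPeak],
    candidates: tuple[str, ...],
    conc: dict[str, float],
    area_tolerance: float,
    reference_order: list[str] | None,
) -> list[PeakAssignment]:
    """Disambiguate a same-signature group by area shares, then elution order."""
    areas = np.array([p.area for p in group])
    concs = np.array([conc[a] for a in candidates])
    area_share = areas / areas.sum()
    conc_share = concs / concs.sum()
    cost = np.abs(
        np.log(area_share)[:, None] - np.log(conc_share)[None, :]
    )
    rows, cols = linear_sum_assignment(cost)
    chosen = {int(r): candidates[int(c)] for r, c in zip(rows, cols)}

    # a peak is area-ambiguous if another peak's area is within tolerance of
    # its own AND their assigned concentrations are also within tolerance —
    # i.e. the areas genuinely cannot tell the two candidates apart
    ambiguous_idx: set[int] = set()
    for i in range(len(group)):
        for j in range(i + 1, len(group)):
            ratio_area = max(areas[i], areas[j]) / min(areas[i], areas[j])
            ci, cj = conc[chosen[i]], conc[chosen[j]]
            ratio_conc = max(ci, cj) / min(ci, cj)
            if ratio_area <= 1.0 + area_tolerance and ratio_conc <= 1.0 + area_tolerance:
                ambiguous_idx.update((i, j))

    if ambiguous_idx and reference_order is not None:
        # order evidence: peaks in rt order map onto candidates in the
        # expected elution order
        order_rank = {a: i for i, a in enumerate(reference_order)}
        if all(a in order_rank for a in candidates):
            amb_sorted = sorted(ambiguous_idx, key=lambda i: group[i].rt_min)
            amb_cands = sorted(
                (chosen[i] for i in ambiguous_idx), key=lambda a: order_rank[a]
            )
            for i, a in zip(amb_sorted, amb_cands):
                chosen[i] = a
            ambiguous_idx = set()

    out = []
    for i, p in enumerate(group):
        if i in ambiguous_idx:
            out.append(
                PeakAssignment(p.rt_min, p.area, None, True, candidates,
                               "indistinguishable-areas")
            )
        else:
            out.append(
                PeakAssignment(p.rt_min, p.area, chosen[i], False, candidates,
                               "area-match" if len(candidates) > 1 else "unique")
            )
    return out


def assignments_to_rows(
    assignments: list[PeakAssignment],
    run_id: str,
    tG_min: float,
    temp_c: float,
    ternary_fraction: float,
    flow_ml_min: float,
) -> pd.DataFrame:
    """Labeled peaks as corner-table rows (ambiguous peaks are dropped)."""
    rows = [
        {
            "run_id": run_id,
            "tG_min": tG_min,
            "temp_c": temp_c,
            "ternary_fraction": ternary_fraction,
            "flow_ml_min": flow_ml_min,
            "analyte": a.analyte,
            "rt_min": a.rt_min,
            "area": a.area,
            "mixture_id": "",
        }
        for a in assignments
        if not a.ambiguous
    ]
    return pd.DataFrame(rows)
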