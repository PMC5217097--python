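"""Event-type schemes for weighted composite-endpoint analysis.

A composite endpoint combines several component outcomes (e.g. a non-fatal
event N and a fatal event F).  Over a fixed horizon (0, tau] a subject's
outcome is summarised by *event types*, which can be defined in four ways:

* ``exhaustive``     - every observable combination of components is its own
                       type (the no-event category is always dropped so that
                       the covariance of the type indicators has full rank);
* ``competing_risks`` - the type of the *first* component event only;
* ``worst_event``    - the most severe component experienced;
* ``marginal``       - one (possibly overlapping) indicator per component.

The last three are linear images of the exhaustive setting: each scheme
carries a 0/1 matrix ``L`` such that scheme probabilities equal
``L @ exhaustive probabilities``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ComponentSet",
    "EventTypeScheme",
    "SubjectHistory",
    "build_scheme",
    "classify_subject",
    "SETTINGS",
]

SETTINGS = ("exhaustive", "competing_risks", "worst_event", "marginal")


@dataclass(frozen=True)
class ComponentSet:
    """Ordered component outcomes, least to most severe, with absorbing flags.

    Components flagged absorbing (fatal) terminate a subject's history; a
    subject can experience each component at most once.
    """

    labels: tuple
    fatal_flags: tuple

    def __init__(self, labels, fatal_flags):
        labels = tuple(labels)
        fatal_flags = tuple(bool(f) for f in fatal_flags)
        if not labels:
            raise ValueError("component set must be nonempty")
        if len(set(labels)) != len(labels):
            raise ValueError("component labels must be unique")
        if len(fatal_flags) != len(labels):
            raise ValueError("fatal_flags must match labels")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "fatal_flags", fatal_flags)


@dataclass(frozen=True)
class SubjectHistory:
    """One subject's observed path: component events plus optional censoring."""

    subject_id: str
    arm: str
    events: tuple  # ((time, component_label), ...) sorted by time
    censor_time: float | None = None

    def __post_init__(self):
        times = [t for t, _ in self.events]
        if any(t <= 0 for t in times):
            raise ValueError("event times must be strictly positive")
        if times != sorted(times):
            raise ValueError("events must be sorted by time")
        if len(set(times)) != len(times):
            raise ValueError(
                "simultaneous same-time transitions are invalid input"
            )
        labels = [lab for _, lab in self.events]
        if len(set(labels)) != len(labels):
            raise ValueError("each component may occur at most once")
        if self.censor_time is not None and times and self.censor_time < times[-1]:
            raise ValueError("censoring must follow the last event")

    @property
    def last_time(self) -> float:
        if self.censor_time is not None:
            return self.censor_time
        return self.events[-1][0] if self.events else 0.0


def _subset_label(subset, components: ComponentSet) -> str:
    """Canonical exhaustive-type label, e.g. 'N+F-' for {N} out of {N, F}."""
    return "".join(
        f"{lab}{'+' if lab in subset else '-'}" for lab in components.labels
    )


def _first_component(subset, components: ComponentSet):
    """First-acquired component of an exhaustive type.

    Absorbing components are necessarily acquired last, so the first event
    of a combination is its least severe non-absorbing member (list order),
    or the absorbing component itself if no other is present.
    """
    nonfatal = [
        lab
        for lab in components.labels
        if lab in subset and not components.fatal_flags[components.labels.index(lab)]
    ]
    if nonfatal:
        return nonfatal[0]
    return next(lab for lab in components.labels if lab in subset)


def _worst_component(subset, components: ComponentSet):
    """Most severe member of a combination (components ordered least to most
    severe)."""
    present = [lab for lab in components.labels if lab in subset]
    return present[-1]


def _default_subsets(components: ComponentSet):
    """All observable component combinations under a fully sequential model:
    any set of non-absorbing components, optionally terminated by a single
    absorbing one.  Ordered by (size, severity)."""
    labels = components.labels
    fatal = [l for l, f in zip(labels, components.fatal_flags) if f]
    nonfatal = [l for l, f in zip(labels, components.fatal_flags) if not f]
    subsets = []
    from itertools import combinations

    for r in range(len(nonfatal) + 1):
        for combo in combinations(nonfatal, r):
            if combo:
                subsets.append(frozenset(combo))
            for fl in fatal:
                subsets.append(frozenset(combo) | {fl})
    key = lambda s: (len(s), tuple(labels.index(l) for l in sorted(s, key=labels.index)))
    return sorted(set(subsets), key=key)


@dataclass(frozen=True)
class EventTypeScheme:
    """A named event-type setting together with its linear map from the
    exhaustive setting."""

    setting: str
    event_types: tuple
    L: np.ndarray  # (K, K_ex) 0/1 matrix
    components: ComponentSet
    exhaustive_types: tuple
    exhaustive_subsets: tuple  # frozensets aligned with exhaustive_types

    @property
    def K(self) -> int:
        return len(self.event_types)

    @property
    def overlapping(self) -> bool:
        return self.setting == "marginal"

    def __post_init__(self):
        L = np.asarray(self.L, dtype=float)
        if not np.all(np.isin(L, (0.0, 1.0))):
            raise ValueError("L must be a 0/1 matrix")
        if L.shape != (len(self.event_types), len(self.exhaustive_types)):
            raise ValueError("L shape inconsistent with event types")
        if self.setting != "marginal" and np.any(L.sum(axis=0) > 1):
            raise ValueError(
                "non-overlapping settings must partition the exhaustive types"
            )


def build_scheme(
    components: ComponentSet, setting: str, subsets=None
) -> EventTypeScheme:
    """Construct an :class:`EventTypeScheme` for the given setting.

    ``subsets`` optionally restricts the exhaustive types to the component
    combinations actually reachable under a particular multistate model
    (unreachable types would make the covariance singular); by default every
    combination observable under a sequential model is included.
    """
    if setting not in SETTINGS:
        raise ValueError(f"unknown setting {setting!r}; expected one of {SETTINGS}")
    if subsets is None:
        subsets = _default_subsets(components)
    subsets = tuple(frozenset(s) for s in subsets)
    if not subsets:
        raise ValueError("no exhaustive event types")
    ex_types = tuple(_subset_label(s, components) for s in subsets)
    K_ex = len(subsets)

    if setting == "exhaustive":
        return EventTypeScheme(
            setting, ex_types, np.eye(K_ex), components, ex_types, subsets
        )

    if setting == "marginal":
        rows, types = [], []
        for lab in components.labels:
            rows.append([1.0 if lab in s else 0.0 for s in subsets])
            types.append(f"{lab}+")
    elif setting == "worst_event":
        rows, types = [], []
        for lab in components.labels:
            row = [1.0 if _worst_component(s, components) == lab else 0.0 for s in subsets]
            if not any(row):
                continue
            rows.append(row)
            idx = components.labels.index(lab)
            more_severe = components.labels[idx + 1 :]
            types.append(f"{lab}+" + "".join(f"{m}-" for m in more_severe))
    else:  # competing_risks
        rows, types = [], []
        for lab in components.labels:
            row = [1.0 if _first_component(s, components) == lab else 0.0 for s in subsets]
            if not any(row):
                continue
            rows.append(row)
            covered = [s for s, r in zip(subsets, row) if r]
            if len(covered) == 1:
                types.append(_subset_label(covered[0], components))
            else:
                types.append(f"{lab}+")
    L = np.array(rows)
    return EventTypeScheme(setting, tuple(types), L, components, ex_types, subsets)


def classify_subject(
    history: SubjectHistory, scheme: EventTypeScheme, tau: float
) -> np.ndarray:
    """0/1 indicator vector of the event types realised in (0, tau].

    Requires complete follow-up: the subject must be observed through tau or
    have experienced an absorbing component before censoring.
    """
    comps = scheme.components
    absorbed = any(
        comps.fatal_flags[comps.labels.index(lab)] for _, lab in history.events
    )
    if history.last_time < tau and not absorbed:
        raise ValueError(
            f"subject {history.subject_id!r} has incomplete follow-up; "
            "use the Aalen-Johansen path"
        )
    realised = frozenset(lab for t, lab in history.events if 0.0 < t <= tau)
    ex_ind = np.zeros(len(scheme.exhaustive_types))
    if realised:
        try:
            idx = scheme.exhaustive_subsets.index(realised)
        except ValueError:
            raise ValueError(
                f"combination {sorted(realised)} is not an exhaustive event "
                "type of this scheme"
            ) from None
        ex_ind[idx] = 1.0
    return scheme.L @ ex_ind
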