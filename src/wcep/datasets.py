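"""Bundled worked-example data.

The enteric-fever trial compared Gatifloxacin with Cefixime for
uncomplicated typhoid.  The composite endpoint "overall treatment failure"
has two exclusive components: acute treatment failure or death (``AF``) and
relapse (``RE``).  Observed frequencies in culture-confirmed patients were
1/92 and 2/92 in the Gatifloxacin arm and 20/77 and 6/77 in the Cefixime
arm.  The trial reported counts over a fixed evaluation window, so the data
are represented as complete-follow-up binary outcomes over a nominal
horizon tau = 1, with events placed mid-interval.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .event_model import ComponentSet, SubjectHistory, build_scheme

__all__ = [
    "ENTERIC_COMPONENTS",
    "ENTERIC_COUNTS",
    "enteric_fever_records",
    "enteric_fever_scheme",
    "enteric_fever_path",
]

# both components are terminal for the endpoint: subjects with an acute
# failure were not evaluated for relapse, so the types are exclusive
ENTERIC_COMPONENTS = ComponentSet(("AF", "RE"), (True, True))

ENTERIC_COUNTS = {
    "Cefixime": {"AF": 20, "RE": 6, "n": 77},
    "Gatifloxacin": {"AF": 1, "RE": 2, "n": 92},
}

TAU = 1.0


def enteric_fever_scheme():
    """Two exclusive event types: acute failure/death and relapse."""
    return build_scheme(ENTERIC_COMPONENTS, "exhaustive")


def enteric_fever_records() -> dict:
    """Reconstructed subject-level records from the printed counts."""
    out = {}
    for arm, counts in ENTERIC_COUNTS.items():
        recs = []
        i = 0
        for label in ("AF", "RE"):
            for _ in range(counts[label]):
                i += 1
                recs.append(
                    SubjectHistory(
                        subject_id=f"{arm[:1]}{i:03d}",
                        arm=arm,
                        events=((0.5, label),),
                        censor_time=None,
                    )
                )
        while i < counts["n"]:
            i += 1
            recs.append(
                SubjectHistory(
                    subject_id=f"{arm[:1]}{i:03d}",
                    arm=arm,
                    events=(),
                    censor_time=TAU,
                )
            )
        out[arm] = recs
    return out


def enteric_fever_path():
    """Path to the bundled event-history CSV."""
    return resources.files("wcep") / "data" / "enteric_fever.csv"
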