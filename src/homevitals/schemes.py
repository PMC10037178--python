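"""Threshold-band scoring schemes for single-domain alerting.

A :class:`ThresholdBand` partitions the real line for one domain into
half-open intervals ``[edge_{i-1}, edge_i)`` (first interval open below,
last open above), each carrying an integer subscore 0-3.  A
:class:`ScoringScheme` bundles one band per scored domain.  Only HR, SBP,
TEMP and SPO2 are ever scored; diastolic pressure and body weight are not
alerting domains and requesting a subscore for them is an error.

The default ``NEWS2`` scheme encodes the published National Early Warning
Score 2 chart for the four home-measurable domains.  The chart prints
integer bands (e.g. pulse 91-110 scores 1); device outputs are continuous,
so each band is encoded as a half-open interval at the printed edges:
41 <= HR < 51 scores 1, 91 <= HR < 111 scores 1, and so on, which
reproduces the integer chart exactly on integer inputs.

The ``MINDER`` scheme is the configurable study-team criterion set: a
single-tier normal/abnormal band per domain.  The thresholds shipped here
are documented placeholders (clinically conventional community cutoffs);
deployments substitute their own via a YAML scheme file, and all
MINDER-tier outputs are therefore scheme-dependent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .model import Domain

#: Domains that may carry threshold bands; DBP and WEIGHT are never scored.
SCORABLE_DOMAINS = (Domain.HR, Domain.SBP, Domain.TEMP, Domain.SPO2)


class UnscoredDomainError(ValueError):
    """Raised when a subscore is requested for a domain the scheme does not score."""


@dataclass(frozen=True)
class ThresholdBand:
    """Ordered threshold bands for one domain.

    ``upper_edges`` are the strictly increasing interval breakpoints; value v
    falls in interval i where ``upper_edges[i-1] <= v < upper_edges[i]``
    (first interval unbounded below, last unbounded above).  ``scores`` has
    one more entry than ``upper_edges``.
    """

    domain: Domain
    upper_edges: tuple[float, ...]
    scores: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.upper_edges) + 1:
            raise ValueError("need exactly len(upper_edges)+1 scores")
        if list(self.upper_edges) != sorted(set(self.upper_edges)):
            raise ValueError("upper_edges must be strictly increasing")
        if not all(0 <= s <= 3 for s in self.scores):
            raise ValueError("subscores must be integers in 0..3")
        if 0 not in self.scores:
            raise ValueError("at least one interval must score 0 (the normal band)")

    def subscore(self, value: float) -> int:
        if not math.isfinite(value):
            raise ValueError(f"non-finite value {value!r}")
        idx = int(np.searchsorted(self.upper_edges, value, side="right"))
        return self.scores[idx]

    def subscore_array(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("non-finite value in stream")
        idx = np.searchsorted(self.upper_edges, values, side="right")
        return np.asarray(self.scores)[idx]


@dataclass(frozen=True)
class ScoringScheme:
    """A named set of threshold bands, one per scored domain."""

    name: str
    bands: dict[Domain, ThresholdBand]

    def __post_init__(self) -> None:
        for dom in self.bands:
            if dom not in SCORABLE_DOMAINS:
                raise UnscoredDomainError(f"{dom} cannot carry threshold bands")

    @property
    def scored_domains(self) -> tuple[Domain, ...]:
        return tuple(self.bands)

    def subscore(self, domain: Domain | str, value: float) -> int:
        domain = Domain(domain)
        band = self.bands.get(domain)
        if band is None:
            raise UnscoredDomainError(f"scheme {self.name!r} does not score {domain}")
        return band.subscore(value)

    @property
    def max_score(self) -> int:
        return max(max(b.scores) for b in self.bands.values())


def _band(domain: Domain, pairs: list[tuple[float | None, int]]) -> ThresholdBand:
    """Build a band from (upper_edge, score) pairs, last edge ``None`` for the
    open-ended top interval."""
    edges = tuple(float(e) for e, _ in pairs[:-1])
    if pairs[-1][0] is not None:
        raise ValueError("last interval must be open-ended (upper_edge null)")
    scores = tuple(int(s) for _, s in pairs)
    return ThresholdBand(domain, edges, scores)


# Published NEWS2 chart, four home-measurable domains, half-open encoding.
NEWS2 = ScoringScheme(
    name="NEWS2",
    bands={
        Domain.HR: _band(
            Domain.HR,
            [(41.0, 3), (51.0, 1), (91.0, 0), (111.0, 1), (131.0, 2), (None, 3)],
        ),
        Domain.SBP: _band(
            Domain.SBP,
            [(91.0, 3), (101.0, 2), (111.0, 1), (220.0, 0), (None, 3)],
        ),
        Domain.TEMP: _band(
            Domain.TEMP,
            [(35.1, 3), (36.1, 1), (38.1, 0), (39.1, 1), (None, 2)],
        ),
        Domain.SPO2: _band(
            Domain.SPO2,
            [(92.0, 3), (94.0, 2), (96.0, 1), (None, 0)],
        ),
    },
)

# Placeholder single-tier study criteria (normal/abnormal); see module
# docstring.  Replace via a scheme YAML for a real deployment.
MINDER = ScoringScheme(
    name="MINDER",
    bands={
        Domain.HR: _band(Domain.HR, [(50.0, 1), (110.0, 0), (None, 1)]),
        Domain.SBP: _band(Domain.SBP, [(100.0, 1), (180.0, 0), (None, 1)]),
        Domain.TEMP: _band(Domain.TEMP, [(35.5, 1), (37.8, 0), (None, 1)]),
        Domain.SPO2: _band(Domain.SPO2, [(94.0, 1), (None, 0)]),
    },
)

BUILTIN_SCHEMES: dict[str, ScoringScheme] = {"news2": NEWS2, "minder": MINDER}


def load_scheme(source: str | Path) -> ScoringScheme:
    """Resolve a scheme by builtin name (``news2``, ``minder``) or YAML path.

    The YAML format mirrors the band encoding: per domain, a list of
    ``[upper_edge, subscore]`` pairs with a ``null`` upper edge on the last,
    open-ended interval::

        name: clinic-A
        bands:
          HR:
            - [50, 1]
            - [110, 0]
            - [null, 2]
    """
    key = str(source).lower()
    if key in BUILTIN_SCHEMES:
        return BUILTIN_SCHEMES[key]
    path = Path(source)
    if not path.exists():
        raise ValueError(f"unknown scheme {source!r}: not a builtin name or readable file")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    bands = {}
    for dom_name, pairs in data["bands"].items():
        dom = Domain(dom_name)
        bands[dom] = _band(dom, [(e, s) for e, s in pairs])
    return ScoringScheme(name=str(data.get("name", path.stem)), bands=bands)
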