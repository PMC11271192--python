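"""Binary risk-factor profiles and the metabolic-syndrome progression graph.

A sample's metabolic-syndrome state is summarised by four binary risk
factors — diabetes (impaired fasting glucose), obesity, dyslipidemia and
hypertension — concatenated into a 4-character code ``"0000"`` ..
``"1111"``.  The code ``0000`` is the asymptomatic reference.  The WHO
rule calls a profile metabolic syndrome when diabetes is present together
with at least two of the other three factors, i.e. exactly the codes
``{1011, 1101, 1110, 1111}``.

Profiles form a 4-dimensional hypercube: each of the 16 states connects
to the 4 states reachable by toggling a single risk factor, giving 32
edges.  :func:`build_profile_graph` annotates that hypercube with
per-profile sample counts and mean risk scores so progression paths from
``0000`` to ``1111`` can be read off.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

RISK_FACTORS = ("diabetes", "obesity", "dyslipidemia", "hypertension")


@dataclass(frozen=True, order=True)
class RiskProfile:
    """One of the 16 binary risk-factor states.

    Bit order is (diabetes, obesity, dyslipidemia, hypertension), so
    ``RiskProfile.from_code("1110")`` is a profile with diabetes, obesity
    and dyslipidemia but no hypertension.
    """

    diabetes: int
    obesity: int
    dyslipidemia: int
    hypertension: int

    def __post_init__(self) -> None:
        for name in RISK_FACTORS:
            bit = getattr(self, name)
            if bit not in (0, 1):
                raise ValueError(f"risk factor {name!r} must be 0 or 1, got {bit!r}")

    @property
    def code(self) -> str:
        return f"{self.diabetes}{self.obesity}{self.dyslipidemia}{self.hypertension}"

    @property
    def n_active(self) -> int:
        return self.diabetes + self.obesity + self.dyslipidemia + self.hypertension

    @classmethod
    def from_code(cls, code: str) -> "RiskProfile":
        if len(code) != 4 or any(c not in "01" for c in code):
            raise ValueError(f"profile code must be 4 characters of 0/1, got {code!r}")
        return cls(*(int(c) for c in code))

    def __str__(self) -> str:
        return self.code


ALL_PROFILES: tuple[RiskProfile, ...] = tuple(
    RiskProfile(*bits) for bits in product((0, 1), repeat=4)
)
ALL_CODES: tuple[str, ...] = tuple(p.code for p in ALL_PROFILES)


def encode_profile(
    diabetes: bool, obesity: bool, dyslipidemia: bool, hypertension: bool
) -> RiskProfile:
    """Encode four presence/absence flags into a :class:`RiskProfile`."""
    return RiskProfile(int(diabetes), int(obesity), int(dyslipidemia), int(hypertension))


def _who_rule(profile: RiskProfile) -> bool:
    # diabetes plus >= 2 of the remaining three factors
    others = profile.obesity + profile.dyslipidemia + profile.hypertension
    return bool(profile.diabetes) and others >= 2


#: Registered MetS definitions: name -> predicate on RiskProfile.
_DEFINITIONS: dict[str, Callable[[RiskProfile], bool]] = {"WHO": _who_rule}

WHO_CODES: frozenset[str] = frozenset(p.code for p in ALL_PROFILES if _who_rule(p))


def register_definition(name: str, member_codes: Iterable[str]) -> None:
    """Register a MetS definition as an explicit set of profile codes.

    Only WHO ships as a built-in rule; other consensus definitions
    (EGIR, NCEP, IDF, ...) can be registered from their code sets.
    """
    codes = {RiskProfile.from_code(c).code for c in member_codes}
    _DEFINITIONS[name] = lambda p, _codes=frozenset(codes): p.code in _codes


def registered_definitions() -> tuple[str, ...]:
    return tuple(sorted(_DEFINITIONS))


def classify_mets(profile: RiskProfile | str, definition: str = "WHO") -> bool:
    """True if *profile* meets the named metabolic-syndrome definition."""
    if definition not in _DEFINITIONS:
        raise KeyError(
            f"unknown MetS definition {definition!r}; "
            f"registered: {', '.join(registered_definitions())}"
        )
    if isinstance(profile, str):
        profile = RiskProfile.from_code(profile)
    return _DEFINITIONS[definition](profile)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def build_profile_graph(
    scores_by_sample: Sequence[float] | np.ndarray,
    profiles_by_sample: Sequence[RiskProfile | str],
) -> nx.Graph:
    """Build the 16-node risk-profile hypercube annotated with sample stats.

    Nodes are the 16 profile codes; each carries ``n_samples``,
    ``mean_score`` (``None`` when the profile has no samples), ``n_active``
    and one boolean flag per registered MetS definition.  Edges join codes
    at Hamming distance 1 (32 in total), each labelled with the risk
    factor that is toggled.
    """
    scores = np.asarray(scores_by_sample, dtype=float)
    if scores.ndim != 1:
        raise ValueError("scores must be one-dimensional")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    codes = [p.code if isinstance(p, RiskProfile) else RiskProfile.from_code(p).code
             for p in profiles_by_sample]
    if len(codes) != scores.size:
        raise ValueError("scores and profiles must have equal length")

    by_code: dict[str, list[float]] = {c: [] for c in ALL_CODES}
    for code, s in zip(codes, scores):
        by_code[code].append(s)

    graph = nx.Graph()
    for profile in ALL_PROFILES:
        members = by_code[profile.code]
        graph.add_node(
            profile.code,
            n_samples=len(members),
            mean_score=float(np.mean(members)) if members else None,
            n_active=profile.n_active,
            **{f"mets_{name}": classify_mets(profile, name) for name in _DEFINITIONS},
        )
    for i, a in enumerate(ALL_CODES):
        for b in ALL_CODES[i + 1:]:
            if _hamming(a, b) == 1:
                toggled = next(k for k in range(4) if a[k] != b[k])
                graph.add_edge(a, b, toggled_factor=RISK_FACTORS[toggled])
    return graph


def graph_to_tables(graph: nx.Graph):
    """Export the profile graph as (nodes, edges) pandas DataFrames."""
    import pandas as pd

    nodes = pd.DataFrame(
        [{"code": c, **attrs} for c, attrs in sorted(graph.nodes(data=True))]
    )
    edges = pd.DataFrame(
        [{"source": a, "target": b, **attrs} for a, b, attrs in sorted(graph.edges(data=True))]
    )
    return nodes, edges
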