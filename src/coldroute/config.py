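"""Configuration: condition vocabularies, penalty scales, numerical knobs.

Road and vehicle conditions are entered as categorical labels; the numeric
penalty attached to each label is a code-level configuration, not user data,
so that all penalties live on one consistent ordinal scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

#: Ordered road-condition vocabulary, best to worst.
ROAD_CONDITION_LABELS: tuple[str, ...] = (
    "fully paved",
    "partially paved",
    "dirt road (good quality)",
    "dirt road (rough quality)",
    "boat access only",
    "foot access only",
    "not accessible",
)

#: Default road penalties (gamma).  "not accessible" carries no penalty value:
#: such arcs are simply unavailable.
DEFAULT_ROAD_PENALTIES: dict[str, float] = {
    "fully paved": 1.0,
    "partially paved": 2.0,
    "dirt road (good quality)": 3.0,
    "dirt road (rough quality)": 5.0,
    "boat access only": 6.0,
    "foot access only": 8.0,
}

#: Ordered vehicle-condition vocabulary, best to worst.
VEHICLE_CONDITION_LABELS: tuple[str, ...] = (
    "very reliable",
    "reliable",
    "somewhat reliable",
    "unreliable",
)

DEFAULT_VEHICLE_PENALTIES: dict[str, float] = {
    "very reliable": 1.0,
    "reliable": 2.0,
    "somewhat reliable": 3.0,
    "unreliable": 4.0,
}

#: Objective forms.  "printed" uses decreasing exponentials
#: exp(-value/mean); "increasing" flips the exponent sign so that longer
#: or riskier arcs cost more.  Both are supported everywhere.
OBJECTIVE_FORMS = ("printed", "increasing")


@dataclass(frozen=True)
class Config:
    """Numeric configuration shared by all solvers.

    Attributes
    ----------
    road_penalties, vehicle_penalties:
        Label -> penalty maps; must cover the closed vocabularies above
        (road map excludes "not accessible").
    objective_form:
        "printed" or "increasing" (see module docstring).
    mu_h_factor2:
        Keep the factor 2 in the mean-transit-time normaliser
        mu_h = sum(2 h) / (|V| |C|^2).  On by default.
    feasibility_tol:
        Absolute tolerance used in feasibility checks (hours / liters).
    """

    road_penalties: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ROAD_PENALTIES)
    )
    vehicle_penalties: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VEHICLE_PENALTIES)
    )
    objective_form: str = "printed"
    mu_h_factor2: bool = True
    feasibility_tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.objective_form not in OBJECTIVE_FORMS:
            raise ValueError(
                f"objective_form must be one of {OBJECTIVE_FORMS}, "
                f"got {self.objective_form!r}"
            )

    def with_form(self, objective_form: str) -> "Config":
        return replace(self, objective_form=objective_form)


DEFAULT_CONFIG = Config()
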