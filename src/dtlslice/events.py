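"""Elementary evolutionary events: costs, names and scenario tags.

The reconciliation model distinguishes 35 event types (rows 0..34). A row is
identified by its index; each row has a short name, a local cost increment
expressed in the seven elementary cost parameters, and a list of *tag
triplets* used when counting events of a given kind in a scenario (tags such
as ``dupl``, ``loss``, ``tr+o`` = transfer out of a tube with retention in the
donor, ``tr-o`` = transfer out without retention, ``loss-`` = loss of the
transferred copy in the donor, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass(frozen=True)
class EventCosts:
    """Nonnegative costs of the elementary events (dimensionless units).

    ``dupl`` and ``loss`` double as the supertree Phase I parameters c_d, c_l.
    The defaults make losses cheapest and gains/transfers costlier; they are a
    package choice (configurable everywhere) rather than canonical values.
    """

    loss: float = 1.0
    dupl: float = 2.0
    gain: float = 3.0
    tr_with: float = 3.0
    tr_without: float = 3.0
    sleep: float = 1.0
    gain_big: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"event cost {f.name!r} must be >= 0, got {v}")

    def mean(self) -> float:
        vals = [getattr(self, f.name) for f in fields(self)]
        return sum(vals) / len(vals)


EVENT_NAMES = (
    "fin", "tr_fin", "ga_fin", "pass", "fork_lr", "fork_rl", "pass_l",
    "pass_r", "nout_l", "nout_r", "out_l", "out_r", "dupl", "dup0", "outd",
    "tr1", "tr2", "ga1", "ga2", "sl", "ga_big", "tr_pass", "ga_pass",
    "tr_lr", "tr_rl", "ga_lr", "ga_rl", "tr_l", "tr_r", "ga_l", "ga_r",
    "tr_dupl", "ga_dupl", "tr_double", "ga_double",
)

N_EVENTS = 35

# Local cost increment of each row, as a tuple of elementary-cost attribute
# names to be summed (child-cell terms are added by the dynamic program).
ROW_INCREMENT = {
    0: (), 1: ("tr_without",), 2: ("gain",), 3: (), 4: (), 5: (),
    6: ("loss",), 7: ("loss",), 8: (), 9: (), 10: (), 11: (),
    12: ("dupl",), 13: (), 14: (),
    15: ("tr_with",), 16: ("tr_with",), 17: ("gain",), 18: ("gain",),
    19: ("sleep",), 20: ("gain_big",), 21: ("tr_without",), 22: ("gain",),
    23: ("tr_without",), 24: ("tr_without",), 25: ("gain",), 26: ("gain",),
    27: ("tr_without", "loss"), 28: ("tr_without", "loss"),
    29: ("gain", "loss"), 30: ("gain", "loss"),
    31: ("tr_without", "dupl"), 32: ("gain", "dupl"),
    33: ("tr_without", "tr_with"), 34: ("gain", "tr_with"),
}


def row_increment(row: int, costs: EventCosts) -> float:
    return sum(getattr(costs, name) for name in ROW_INCREMENT[row])


# Scenario tags (second-scenario vocabulary).
TAGS = frozenset({
    "gain", "gain_big", "dupl", "loss", "sleep",
    "tr+o", "tr-o", "tr+i", "tr-i", "loss-",
})

# Default tag set of the second-scenario cost: gains, origin of the family,
# duplications, losses, transfers out of a tube, loss of the copy in the donor.
DEFAULT_SCENARIO_TAGS = frozenset(
    {"gain", "gain_big", "dupl", "loss", "tr-o", "tr+o", "loss-"}
)

# Elementary cost charged per tag when computing cost expectations.
TAG_COST_ATTR = {
    "gain": "gain", "gain_big": "gain_big", "dupl": "dupl", "loss": "loss",
    "sleep": "sleep", "tr+o": "tr_with", "tr+i": "tr_with",
    "tr-o": "tr_without", "tr-i": "tr_without", "loss-": "loss",
}


def tag_cost(tag: str, costs: EventCosts) -> float:
    return getattr(costs, TAG_COST_ATTR[tag])


# Tag-triplet templates per row: (tag, edge-ref, tube-ref). Edge refs:
# "e" (the edge of the vertex), "e1"/"e2" (its children), "e1&e2" (composite,
# contributions halved per member). Tube refs: "d" (the vertex tube), "d1"/"d2"
# (children of d), "d'" / "d''" (minimal parameters), "d'1"/"d'2" (children of
# the chosen d'), "x" (the terminal tube cohered with e), "d'&d''" (composite).
TAG_TABLE = {
    0: (),
    1: (("tr-o", "e", "d"), ("tr-i", "e", "x"), ("loss-", "e", "d")),
    2: (("gain", "e", "x"),),
    3: (), 4: (), 5: (),
    6: (("loss", "e", "d2"),),
    7: (("loss", "e", "d1"),),
    8: (), 9: (), 10: (), 11: (),
    12: (("dupl", "e", "d"),),
    13: (), 14: (),
    15: (("tr+o", "e1", "d"), ("tr+i", "e1", "d'")),
    16: (("tr+o", "e2", "d"), ("tr+i", "e2", "d'")),
    17: (("gain", "e1", "d'"),),
    18: (("gain", "e2", "d'"),),
    19: (("sleep", "e", "d"),),
    20: (("gain_big", "e", "d'"),),
    21: (("tr-o", "e", "d"), ("tr-i", "e", "d'"), ("loss-", "e", "d")),
    22: (("gain", "e", "d'"),),
    23: (("tr-o", "e", "d"), ("tr-i", "e", "d'"), ("loss-", "e", "d")),
    24: (("tr-o", "e", "d"), ("tr-i", "e", "d'"), ("loss-", "e", "d")),
    25: (("gain", "e", "d'"),),
    26: (("gain", "e", "d'"),),
    27: (("tr-o", "e", "d"), ("tr-i", "e", "d'"), ("loss-", "e", "d"),
         ("loss", "e", "d'2")),
    28: (("tr-o", "e", "d"), ("tr-i", "e", "d'"), ("loss-", "e", "d"),
         ("loss", "e", "d'1")),
    29: (("gain", "e", "d'"), ("loss", "e", "d'2")),
    30: (("gain", "e", "d'"), ("loss", "e", "d'1")),
    31: (("tr-o", "e", "d"), ("tr-i", "e", "d'"), ("loss-", "e", "d"),
         ("dupl", "e", "d'")),
    32: (("gain", "e", "d'"), ("dupl", "e", "d'")),
    33: (("tr-o", "e", "d"), ("loss-", "e", "d"), ("tr-i", "e", "d'&d''"),
         ("tr+o", "e1&e2", "d'&d''"), ("tr+i", "e1&e2", "d'&d''")),
    34: (("gain", "e", "d'&d''"), ("tr+o", "e1&e2", "d'&d''"),
         ("tr+i", "e1&e2", "d'&d''")),
}
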