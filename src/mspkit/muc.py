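"""Maritime Use Conflict (MUC) analysis after the COEXIST methodology.

Each human use is characterized by four attributes — vertical scale (which
part of the water column it occupies), spatial domain, temporal domain and
mobility.  Rule tables map the attribute combination of a pair of uses to a
potential conflict score from 0 (no conflict) to 6 (very high conflict):
uses that never share a vertical domain cannot conflict, while persistent,
spatially extensive, immobile co-located uses conflict most.  The per-cell
MUC score is the sum of the pairwise potential scores over all pairs of
uses present in that cell.

The default :class:`RuleSet` is a reconstruction of the qualitative COEXIST
logic (the original calibration tables live in the COEXIST project reports);
it is a plain configuration object so published tables can be substituted
verbatim via :meth:`RuleSet.from_dict`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import AnalysisGrid, GridLayer, GridError

__all__ = [
    "VERTICAL_DOMAINS",
    "SPATIAL_DOMAINS",
    "TEMPORAL_DOMAINS",
    "MOBILITIES",
    "UseAttributes",
    "RuleSet",
    "default_ruleset",
    "MUCResult",
    "potential_conflict",
    "conflict_matrix",
    "presence_layers",
    "muc_map",
    "enumerate_attribute_profiles",
]

VERTICAL_DOMAINS = ("surface", "water_column", "seabed")
SPATIAL_DOMAINS = ("local", "large")
TEMPORAL_DOMAINS = ("seasonal", "year_round")
MOBILITIES = ("mobile", "fixed")


@dataclass(frozen=True)
class UseAttributes:
    """The four COEXIST attributes of one human use."""

    vertical_domain: frozenset
    spatial_domain: str
    temporal_domain: str
    mobility: str

    def __post_init__(self):
        vd = frozenset(
            self.vertical_domain
            if not isinstance(self.vertical_domain, str)
            else [self.vertical_domain]
        )
        object.__setattr__(self, "vertical_domain", vd)
        if not vd:
            raise ValueError("vertical_domain must be a non-empty set")
        bad = vd - set(VERTICAL_DOMAINS)
        if bad:
            raise ValueError(f"unknown vertical domain(s) {sorted(bad)}; "
                             f"choose from {VERTICAL_DOMAINS}")
        if self.spatial_domain not in SPATIAL_DOMAINS:
            raise ValueError(f"spatial_domain {self.spatial_domain!r} not in {SPATIAL_DOMAINS}")
        if self.temporal_domain not in TEMPORAL_DOMAINS:
            raise ValueError(f"temporal_domain {self.temporal_domain!r} not in {TEMPORAL_DOMAINS}")
        if self.mobility not in MOBILITIES:
            raise ValueError(f"mobility {self.mobility!r} not in {MOBILITIES}")


def _pair_table(high: str, low: str, both_high: int, mixed: int, both_low: int) -> dict:
    return {
        frozenset([high]): both_high,
        frozenset([high, low]): mixed,
        frozenset([low]): both_low,
    }


@dataclass(frozen=True)
class RuleSet:
    """Additive conflict rule tables gated by vertical-domain overlap.

    Each table maps the unordered pair of attribute values of two uses to an
    additive score component; the total is ``gate * (mobility + spatial +
    temporal)`` where the gate is 1 when the vertical domains intersect and
    0 otherwise.  With the default component range {0, 1, 2} the attainable
    total spans 0..6.
    """

    mobility: dict = field(default_factory=lambda: _pair_table("fixed", "mobile", 2, 1, 0))
    spatial: dict = field(default_factory=lambda: _pair_table("large", "local", 2, 1, 0))
    temporal: dict = field(default_factory=lambda: _pair_table("year_round", "seasonal", 2, 1, 0))

    def score(self, a: UseAttributes, b: UseAttributes) -> int:
        if not (a.vertical_domain & b.vertical_domain):
            return 0
        total = (
            self.mobility[frozenset([a.mobility, b.mobility])]
            + self.spatial[frozenset([a.spatial_domain, b.spatial_domain])]
            + self.temporal[frozenset([a.temporal_domain, b.temporal_domain])]
        )
        return int(total)

    @classmethod
    def from_dict(cls, d: dict) -> "RuleSet":
        """Build a rule set from ``{"mobility": {"fixed|fixed": 2, ...}, ...}``
        where keys are the two attribute values joined by ``|``."""

        def parse(table: dict) -> dict:
            return {frozenset(k.split("|")): int(v) for k, v in table.items()}

        return cls(
            mobility=parse(d["mobility"]),
            spatial=parse(d["spatial"]),
            temporal=parse(d["temporal"]),
        )

    def to_dict(self) -> dict:
        def dump(table: dict) -> dict:
            return {"|".join(sorted(k)): v for k, v in sorted(
                table.items(), key=lambda kv: sorted(kv[0]))}

        return {"mobility": dump(self.mobility), "spatial": dump(self.spatial),
                "temporal": dump(self.temporal)}


def default_ruleset() -> RuleSet:
    return RuleSet()


def potential_conflict(a: UseAttributes, b: UseAttributes,
                       rules: RuleSet | None = None) -> int:
    """Potential conflict score of a pair of uses: an integer in [0, 6],
    symmetric, and 0 whenever the vertical domains are disjoint."""
    rules = rules or default_ruleset()
    return rules.score(a, b)


def enumerate_attribute_profiles():
    """Every valid attribute profile: non-empty vertical subsets x the three
    binary vocabularies (7 * 2 * 2 * 2 = 56 profiles)."""
    vertical_subsets = [
        frozenset(c)
        for r in range(1, len(VERTICAL_DOMAINS) + 1)
        for c in itertools.combinations(VERTICAL_DOMAINS, r)
    ]
    for vd, sd, td, mob in itertools.product(
        vertical_subsets, SPATIAL_DOMAINS, TEMPORAL_DOMAINS, MOBILITIES
    ):
        yield UseAttributes(vd, sd, td, mob)


def conflict_matrix(use_attributes: dict, rules: RuleSet | None = None) -> pd.DataFrame:
    """Score every unordered pair of uses; returns a symmetric use x use
    DataFrame with a zero diagonal (self-pairs are excluded from accumulation)."""
    names = list(use_attributes)
    if len(names) != len(set(names)):
        raise ValueError("duplicate use names")
    if not names:
        raise ValueError("need at least one use")
    rules = rules or default_ruleset()
    m = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a, b in itertools.combinations(names, 2):
        s = rules.score(use_attributes[a], use_attributes[b])
        m.loc[a, b] = s
        m.loc[b, a] = s
    return m


def presence_layers(use_layers: dict, threshold: float = 0.0) -> dict:
    """Binary presence/absence per use: present iff intensity > threshold;
    nodata counts as absent."""
    out = {}
    for name, layer in use_layers.items():
        present = (layer.filled(0.0) > threshold).astype(np.float64)
        out[name] = layer.copy(name=name, values=present)
    return out


@dataclass
class MUCResult:
    """Total MUC score map plus its decomposition into use-pair contributions."""

    score_map: GridLayer
    pair_contributions: pd.DataFrame  # use_a, use_b, score_sum, cell_count
    provenance: dict = field(default_factory=dict)


def muc_map(presence: dict, matrix: pd.DataFrame, grid: AnalysisGrid) -> MUCResult:
    """Accumulate pairwise conflict over co-occurring uses per cell.

    Per cell, score = sum over unordered pairs (a, b) of uses both present
    of ``matrix[a, b]``.  Cells outside the grid's area mask are nodata.
    """
    names = list(presence)
    missing = [n for n in names if n not in matrix.index]
    if missing:
        raise GridError(f"presence layer(s) {missing} not in the conflict matrix")
    for n in names:
        if not presence[n].grid.is_aligned(grid):
            raise GridError(f"presence layer {n!r} is not aligned to the grid")

    score = np.zeros(grid.shape, dtype=np.float64)
    rows = []
    for a, b in itertools.combinations(names, 2):
        s = float(matrix.loc[a, b])
        both = presence[a].filled(0.0) * presence[b].filled(0.0)
        in_area = both * grid.area_mask
        score += s * both
        n_cells = int(in_area.sum())
        rows.append({"use_a": a, "use_b": b, "score_sum": s * n_cells,
                     "cell_count": n_cells})
    score[~grid.area_mask] = np.nan
    layer = GridLayer("muc", score, grid)
    table = pd.DataFrame(rows, columns=["use_a", "use_b", "score_sum", "cell_count"])
    return MUCResult(score_map=layer, pair_contributions=table)
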