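"""Default marker panel, subset archetypes and bubble-assignment rules.

The twelve B-cell subsets modelled here are the ones recognisable in human
secondary lymphoid tissue: transitional, naive, the CD27-CD45RB+ marginal-zone
precursor, CD27+IgM+IgD+ marginal-zone (MZ) cells, CD27+IgM+IgD- "IgM-only"
cells, CD27+ class-switched memory (IgG+ or IgA+), CD27- switched memory,
CD27-IgM+IgD- cells, germinal-centre (GC) cells, plasmablasts, and a residual
"other" bucket.

Archetype locations live on the arcsinh-transformed intensity scale.  The
precursor archetype encodes the phenotypic shift that distinguishes it from
naive B cells: higher CD24, IgM, CD45 and CD45RB; lower BCMA, HLA-DR, IgD and
CD38.  Rule thresholds are midpoints between the archetype locations they
separate, which is appropriate for the synthetic scale only; real data need
user-supplied thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Full suspension panel (arcsinh scale).  Order is the canonical column order.
PANEL: list[str] = [
    "CD19", "CD20", "CD3", "CD14", "CD45", "CD10", "CD24", "CD27", "CD38",
    "CD45RB", "IgM", "IgD", "IgG", "IgA", "HLA-DR", "BCMA", "CD21", "CD180",
]

#: Markers used for the 2-D embedding of suspension data (subset-defining set).
EMBED_MARKERS: list[str] = [
    "CD10", "CD24", "CD27", "CD38", "IgA", "IgD", "IgM", "IgG", "HLA-DR",
]

SUBSET_NAMES: list[str] = [
    "transitional", "naive", "precursor", "mz", "igm_only", "csm_igg",
    "csm_iga", "cd27neg_switched", "cd27neg_igm_only", "gc", "plasmablast",
    "other",
]

_B = {"CD19": 2.8, "CD20": 2.8, "CD3": 0.3, "CD14": 0.3, "CD45": 2.7}
_LO = 0.4

# Per-subset location parameters (arcsinh scale); unlisted markers default low.
ARCHETYPE_LOCS: dict[str, dict[str, float]] = {
    "transitional": {**_B, "CD10": 2.6, "CD24": 3.2, "CD27": 0.4, "CD38": 3.0,
                     "CD45RB": 0.4, "IgM": 2.4, "IgD": 2.6, "IgG": 0.3,
                     "IgA": 0.3, "HLA-DR": 2.4, "BCMA": 1.0, "CD21": 1.2, "CD180": 1.5},
    "naive": {**_B, "CD10": 0.4, "CD24": 1.4, "CD27": 0.4, "CD38": 1.6,
              "CD45RB": 0.4, "IgM": 1.9, "IgD": 2.9, "IgG": 0.3, "IgA": 0.3,
              "HLA-DR": 2.5, "BCMA": 1.2, "CD21": 1.8, "CD180": 1.8},
    "precursor": {**_B, "CD45": 3.1, "CD10": 0.4, "CD24": 2.4, "CD27": 0.4,
                  "CD38": 1.0, "CD45RB": 2.7, "IgM": 2.7, "IgD": 2.2,
                  "IgG": 0.3, "IgA": 0.3, "HLA-DR": 2.0, "BCMA": 0.7, "CD21": 2.6, "CD180": 2.6},
    "mz": {**_B, "CD10": 0.4, "CD24": 2.4, "CD27": 2.7, "CD38": 1.2,
           "CD45RB": 2.7, "IgM": 2.7, "IgD": 2.2, "IgG": 0.3, "IgA": 0.3,
           "HLA-DR": 2.2, "BCMA": 1.2, "CD21": 2.8, "CD180": 2.8},
    "igm_only": {**_B, "CD10": 0.4, "CD24": 2.0, "CD27": 2.7, "CD38": 1.2,
                 "CD45RB": 2.4, "IgM": 2.7, "IgD": 0.4, "IgG": 0.3, "IgA": 0.3,
                 "HLA-DR": 2.2, "BCMA": 1.2, "CD21": 1.6, "CD180": 1.2},
    "csm_igg": {**_B, "CD10": 0.4, "CD24": 2.0, "CD27": 2.7, "CD38": 1.2,
                "CD45RB": 2.0, "IgM": 0.4, "IgD": 0.4, "IgG": 2.7, "IgA": 0.3,
                "HLA-DR": 2.3, "BCMA": 1.2, "CD21": 1.6, "CD180": 1.0},
    "csm_iga": {**_B, "CD10": 0.4, "CD24": 2.0, "CD27": 2.7, "CD38": 1.2,
                "CD45RB": 2.0, "IgM": 0.4, "IgD": 0.4, "IgG": 0.3, "IgA": 2.7,
                "HLA-DR": 2.3, "BCMA": 1.2, "CD21": 1.6, "CD180": 1.0},
    "cd27neg_switched": {**_B, "CD10": 0.4, "CD24": 1.6, "CD27": 0.4,
                         "CD38": 1.4, "CD45RB": 0.8, "IgM": 0.4, "IgD": 0.4,
                         "IgG": 2.4, "IgA": 0.3, "HLA-DR": 2.3, "BCMA": 1.0, "CD21": 1.5, "CD180": 1.2},
    "cd27neg_igm_only": {**_B, "CD10": 0.4, "CD24": 1.6, "CD27": 0.4,
                         "CD38": 1.3, "CD45RB": 0.8, "IgM": 2.5, "IgD": 0.4,
                         "IgG": 0.3, "IgA": 0.3, "HLA-DR": 2.3, "BCMA": 1.0, "CD21": 1.5, "CD180": 1.2},
    "gc": {**_B, "CD20": 3.0, "CD10": 2.7, "CD24": 0.7, "CD27": 1.9,
           "CD38": 3.1, "CD45RB": 1.0, "IgM": 1.4, "IgD": 0.4, "IgG": 1.0,
           "IgA": 0.8, "HLA-DR": 2.7, "BCMA": 1.0, "CD21": 0.8, "CD180": 0.8},
    "plasmablast": {"CD19": 1.9, "CD20": 0.5, "CD3": 0.3, "CD14": 0.3,
                    "CD45": 2.4, "CD10": 0.5, "CD24": 0.4, "CD27": 2.9,
                    "CD38": 3.7, "CD45RB": 1.0, "IgM": 0.6, "IgD": 0.3,
                    "IgG": 1.0, "IgA": 1.0, "HLA-DR": 1.4, "BCMA": 2.6, "CD21": 0.3, "CD180": 0.3},
}

DEFAULT_SCALE = 0.35

# Midpoint thresholds on the synthetic arcsinh scale.
THRESH: dict[str, float] = {
    "pos": 1.6,        # generic low (0.4) vs high (2.8) midpoint
    "CD38_hi": 2.3,    # GC/transitional CD38-bright vs memory-range CD38
    "CD38_pb": 3.4,    # plasmablast CD38 (3.7) vs GC CD38 (3.1)
    "CD24_hi": 1.9,    # precursor CD24 (2.4) vs naive CD24 (1.4)
    "CD45RB_hi": 1.55, # precursor/MZ CD45RB (2.7) vs naive (0.4)
}


@dataclass(frozen=True)
class Condition:
    marker: str
    op: str  # "gt" | "lt"
    threshold: float

    def __call__(self, medians: dict[str, float]) -> bool:
        if self.marker not in medians:
            raise KeyError(f"rule references unknown marker {self.marker!r}")
        v = medians[self.marker]
        return v > self.threshold if self.op == "gt" else v < self.threshold


@dataclass(frozen=True)
class SubsetRule:
    """Predicate over node medians: all ``conditions`` and >=1 of ``any_of``."""

    name: str
    conditions: tuple[Condition, ...]
    any_of: tuple[Condition, ...] = field(default=())

    def matches(self, medians: dict[str, float]) -> bool:
        if not all(c(medians) for c in self.conditions):
            return False
        if self.any_of:
            return any(c(medians) for c in self.any_of)
        return True


def _c(marker: str, op: str, thr: float) -> Condition:
    return Condition(marker, op, thr)


def default_subset_rules() -> list[SubsetRule]:
    """Suspension-panel rules in a fixed priority order.

    Evaluated first-match-wins; nodes matching nothing fall through to
    "other".  A CD19-low / CD3-high / CD14-high escape clause sits first so
    non-B events can never claim a B-cell subset.
    """
    t = THRESH["pos"]
    return [
        SubsetRule("other", (), (_c("CD19", "lt", t), _c("CD3", "gt", t),
                                 _c("CD14", "gt", t))),
        SubsetRule("plasmablast", (_c("CD38", "gt", THRESH["CD38_pb"]),
                                   _c("CD20", "lt", t))),
        SubsetRule("gc", (_c("CD10", "gt", t),
                          _c("CD38", "gt", THRESH["CD38_hi"]),
                          _c("IgD", "lt", t))),
        SubsetRule("transitional", (_c("CD10", "gt", t), _c("IgD", "gt", t))),
        SubsetRule("precursor", (_c("CD27", "lt", t), _c("IgM", "gt", t),
                                 _c("IgD", "gt", t),
                                 _c("CD45RB", "gt", THRESH["CD45RB_hi"]))),
        SubsetRule("mz", (_c("CD27", "gt", t), _c("IgM", "gt", t),
                          _c("IgD", "gt", t))),
        SubsetRule("igm_only", (_c("CD27", "gt", t), _c("IgM", "gt", t),
                                _c("IgD", "lt", t))),
        SubsetRule("csm_igg", (_c("CD27", "gt", t), _c("IgG", "gt", t))),
        SubsetRule("csm_iga", (_c("CD27", "gt", t), _c("IgA", "gt", t))),
        SubsetRule("cd27neg_switched", (_c("CD27", "lt", t),
                                        _c("IgM", "lt", t),
                                        _c("IgD", "lt", t)),
                   (_c("IgG", "gt", t), _c("IgA", "gt", t))),
        SubsetRule("cd27neg_igm_only", (_c("CD27", "lt", t),
                                        _c("IgM", "gt", t),
                                        _c("IgD", "lt", t))),
        SubsetRule("naive", (_c("CD27", "lt", t), _c("IgD", "gt", t))),
    ]


# ---------------------------------------------------------------- imaging ---

#: Imaging panel: nine B-cell subset markers plus lineage/structure channels.
IMC_CHANNELS: list[str] = [
    "CD19", "CD20", "CD3", "CD45", "cytokeratin", "CD10", "CD24", "CD27",
    "CD38", "CD45RB", "IgM", "IgD",
]

#: Stage-2 markers (B-cell subset designation on pixels).
IMC_B_MARKERS: list[str] = [
    "CD10", "CD19", "CD20", "CD24", "CD27", "CD38", "CD45RB", "IgM", "IgD",
]


def imc_subset_rules() -> list[SubsetRule]:
    """Pixel-node rules over the imaging panel (no IgG/IgA channels).

    Class-switched memory is identified as CD27+IgM-IgD- since switched
    isotypes are not imaged.
    """
    t = THRESH["pos"]
    return [
        SubsetRule("other", (), (_c("CD19", "lt", t), _c("CD20", "lt", t))),
        SubsetRule("gc", (_c("CD10", "gt", t),
                          _c("CD38", "gt", THRESH["CD38_hi"]))),
        SubsetRule("precursor", (_c("CD27", "lt", t), _c("IgM", "gt", t),
                                 _c("IgD", "gt", t),
                                 _c("CD45RB", "gt", THRESH["CD45RB_hi"]))),
        SubsetRule("mz", (_c("CD27", "gt", t), _c("IgM", "gt", t),
                          _c("IgD", "gt", t))),
        SubsetRule("csm", (_c("CD27", "gt", t), _c("IgM", "lt", t),
                           _c("IgD", "lt", t))),
        SubsetRule("igm_only", (_c("CD27", "gt", t), _c("IgM", "gt", t),
                                _c("IgD", "lt", t))),
        SubsetRule("naive", (_c("CD27", "lt", t), _c("IgD", "gt", t))),
    ]
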