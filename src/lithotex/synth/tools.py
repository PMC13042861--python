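"""Domain types for the synthetic carving study.

Tool active parts, skill presets, modality specifications (ordered
technique steps) and the full experimental design enumeration: 19
modalities (pecking, scraping, polishing, engraving and their
superimpositions) times five participants, i.e. 95 trials.

Skill presets encode three contracts that the analysis is designed to
recover: experts orient their gestures more consistently (higher von Mises
concentration kappa), cover the surface more uniformly, and space/size
their marks more regularly (lower coefficient of variation). The preset
numbers are calibration knobs fixed in one place; only their ordering is a
contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class ToolProfile:
    """Geometry of a tool's active part as it imprints the stone."""

    name: str
    contact_kind: str  # point | edge | cobble | skin | sand
    imprint_eccentricity: float = 1.0  # >= 1; elongation of impact marks
    imprint_radius_mean: float = 0.5  # mm
    imprint_depth_mean: float = 0.2  # mm
    striation_depth_mean: float = 0.02  # mm

    def __post_init__(self):
        if self.contact_kind not in {"point", "edge", "cobble", "skin", "sand"}:
            raise DesignError(f"unknown contact kind {self.contact_kind!r}")
        if self.imprint_eccentricity < 1:
            raise DesignError("imprint eccentricity must be >= 1")
        for f_ in ("imprint_radius_mean", "imprint_depth_mean", "striation_depth_mean"):
            if getattr(self, f_) <= 0:
                raise DesignError(f"{f_} must be > 0")


@dataclass(frozen=True)
class SkillLevel:
    label: str
    gesture_concentration: float  # von Mises kappa of stroke/impact orientations
    coverage_uniformity: float  # [0, 1]
    spacing_cv: float  # coefficient of variation of mark spacing/size

    def __post_init__(self):
        if self.gesture_concentration < 0:
            raise DesignError("kappa must be >= 0")
        if not 0 <= self.coverage_uniformity <= 1:
            raise DesignError("coverage uniformity in [0, 1]")
        if self.spacing_cv < 0:
            raise DesignError("spacing CV must be >= 0")


SKILL_PRESETS = {
    "novice": SkillLevel("novice", gesture_concentration=2.0, coverage_uniformity=0.5, spacing_cv=0.6),
    "intermediate": SkillLevel("intermediate", gesture_concentration=8.0, coverage_uniformity=0.7, spacing_cv=0.35),
    "expert": SkillLevel("expert", gesture_concentration=32.0, coverage_uniformity=0.9, spacing_cv=0.15),
}

# Tool set: one profile per active part of the experimental modalities.
TOOLS = {
    "pick_point": ToolProfile("pick_point", "point", 3.4, 0.8, 0.35, 0.03),
    "cobble": ToolProfile("cobble", "cobble", 1.2, 0.9, 0.25, 0.045),
    "broken_blade": ToolProfile("broken_blade", "point", 2.2, 0.55, 0.30, 0.03),
    "blade_edge": ToolProfile("blade_edge", "edge", 1.0, 0.18, 0.10, 0.05),
    "endscraper": ToolProfile("endscraper", "edge", 1.0, 0.18, 0.12, 0.06),
    "burin_point": ToolProfile("burin_point", "point", 1.5, 0.30, 0.40, 0.03),
    "flake_edge": ToolProfile("flake_edge", "edge", 1.0, 0.12, 0.08, 0.03),
    "skin": ToolProfile("skin", "skin", 1.0, 0.15, 0.01, 0.022),
    "wet_sand": ToolProfile("wet_sand", "sand", 1.0, 0.15, 0.01, 0.028),
}

TECHNIQUES = {
    "saw",
    "peck_direct",
    "peck_indirect",
    "scrape",
    "polish",
    "engrave_single",
    "engrave_multi",
}

#: broad class used as the label of a modality (first applied class wins for
#: superimpositions ending in finishing steps; composites keep full code)
TECHNIQUE_CLASS = {
    "saw": "control",
    "peck_direct": "pecking",
    "peck_indirect": "pecking",
    "scrape": "scraping",
    "polish": "polishing",
    "engrave_single": "engraving",
    "engrave_multi": "engraving",
}


@dataclass(frozen=True)
class ModalityStep:
    technique: str
    tool: ToolProfile
    minutes: float = 5.0

    def __post_init__(self):
        if self.technique not in TECHNIQUES:
            raise DesignError(f"unknown technique {self.technique!r}")
        if self.minutes < 0:
            raise DesignError("duration must be >= 0")


@dataclass(frozen=True)
class ModalitySpec:
    code: str
    steps: tuple
    class_override: str | None = None  # e.g. polishing modalities include a
    # scraping preparation pass but are still labelled "polishing"

    def __post_init__(self):
        if not self.steps:
            raise DesignError("modality needs at least one step")

    @property
    def technique_class(self) -> str:
        if self.class_override:
            return self.class_override
        classes = [TECHNIQUE_CLASS[s.technique] for s in self.steps]
        return classes[0] if len(set(classes)) == 1 else "composite"


@dataclass(frozen=True)
class Participant:
    pid: str
    skill: SkillLevel


@dataclass
class StudyDesign:
    modalities: list
    participants: list
    seed: int = 0

    def __post_init__(self):
        codes = [m.code for m in self.modalities]
        if len(set(codes)) != len(codes):
            raise DesignError("modality codes must be unique")
        pids = [p.pid for p in self.participants]
        if len(set(pids)) != len(pids):
            raise DesignError("duplicate participant ids")

    @property
    def n_trials(self) -> int:
        return len(self.modalities) * len(self.participants)


def _m(code: str, *steps, class_override: str | None = None) -> ModalitySpec:
    return ModalitySpec(
        code, tuple(ModalityStep(t, TOOLS[tool]) for t, tool in steps), class_override
    )


def _polish_modality(code: str, medium: str) -> ModalitySpec:
    # polishing squares were scraped beforehand to give a regular surface
    # to polish; the modality is still a polishing observation
    return _m(
        code, ("scrape", "blade_edge"), ("polish", medium), class_override="polishing"
    )


def experimental_modalities() -> list:
    """The 19 experimental modalities: 12 single technique+tool pairs and 7
    sequential combinations."""
    return [
        # pecking, direct percussion
        _m("PDPP", ("peck_direct", "pick_point")),
        _m("PDPC", ("peck_direct", "cobble")),
        # pecking, indirect percussion
        _m("PIPP", ("peck_indirect", "pick_point")),
        _m("PIPB", ("peck_indirect", "broken_blade")),
        # scraping
        _m("ScB", ("scrape", "blade_edge")),
        _m("ScS", ("scrape", "endscraper")),
        # engraving, multiple strokes
        _m("EmsB", ("engrave_multi", "burin_point")),
        _m("EmsF", ("engrave_multi", "flake_edge")),
        _m("EmsBl", ("engrave_multi", "blade_edge")),
        # polishing (applied to a freshly scraped surface, as in the protocol)
        _polish_modality("PoC", "cobble"),
        _polish_modality("PoS", "skin"),
        _polish_modality("PoHS", "wet_sand"),
        # superimpositions
        _m("PDP+EmsB", ("peck_direct", "broken_blade"), ("engrave_multi", "burin_point")),
        _m("PDP+EmsP", ("peck_direct", "broken_blade"), ("engrave_multi", "pick_point")),
        _m("PSc", ("peck_direct", "pick_point"), ("scrape", "endscraper")),
        _m(
            "PDP+Sc+Po+Ess",
            ("peck_direct", "pick_point"),
            ("scrape", "endscraper"),
            ("polish", "skin"),
            ("engrave_single", "blade_edge"),
        ),
        _m(
            "PDP+Sc+Po+Ems",
            ("peck_direct", "pick_point"),
            ("scrape", "endscraper"),
            ("polish", "skin"),
            ("engrave_multi", "blade_edge"),
        ),
        _m(
            "PDP+Sc+Ess+Po",
            ("peck_direct", "pick_point"),
            ("scrape", "endscraper"),
            ("engrave_single", "blade_edge"),
            ("polish", "skin"),
        ),
        _m(
            "PDP+Sc+Ems+Po",
            ("peck_direct", "pick_point"),
            ("scrape", "endscraper"),
            ("engrave_multi", "blade_edge"),
            ("polish", "skin"),
        ),
    ]


def default_participants() -> list:
    """Five participants per phase: two novices, two intermediates, one expert."""
    return [
        Participant("novice_1", SKILL_PRESETS["novice"]),
        Participant("novice_2", SKILL_PRESETS["novice"]),
        Participant("intermediate_1", SKILL_PRESETS["intermediate"]),
        Participant("intermediate_2", SKILL_PRESETS["intermediate"]),
        Participant("expert_1", SKILL_PRESETS["expert"]),
    ]


def full_study_design(seed: int = 0) -> StudyDesign:
    """19 modalities x 5 participants = 95 trials."""
    return StudyDesign(experimental_modalities(), default_participants(), seed=seed)


def three_technique_design(n_per_class: int = 30, skill: str = "intermediate", seed: int = 0) -> StudyDesign:
    """One pecking, one scraping and one polishing modality, replicated over
    ``n_per_class`` synthetic participants of a single skill preset; the
    workhorse of the technique-recovery analyses."""
    modalities = [
        _m("PDPP", ("peck_direct", "pick_point")),
        _m("ScS", ("scrape", "endscraper")),
        _polish_modality("PoS", "skin"),
    ]
    participants = [Participant(f"{skill}_{i}", SKILL_PRESETS[skill]) for i in range(n_per_class)]
    return StudyDesign(modalities, participants, seed=seed)
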