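"""Structure table, breathing presets and the respiratory motion–time curve.

Every tissue in the phantom belongs to one of four modeling categories:

I
    Key abdominal organs with patient-specific anatomical detail.  They are
    composited as a uniform base intensity ``A`` plus a deformably mapped
    detail texture rescaled to mean ``B`` (organ mean = A + B).
II
    Large featureless soft-tissue volumes (muscle, background body tissue,
    static marrow, intestine wall): textured by iterative patch transplant
    from a donor muscle region, then composited with the same A + B rule.
III
    Air-dominated structures (lungs, airway, intestinal air, esophagus wall,
    ambient air): uniform intensity ``A``; lungs and intestinal air receive
    additive Rayleigh-distributed noise.
IV
    Bony structures: placeholder soft tissue in the reference volume, then
    re-rendered with their uniform ``A`` at every phase from the warped
    labels (bone displacement fields are untrustworthy at tissue interfaces).

``kappa_si`` / ``kappa_ap`` are per-structure fractions of the preset's
diaphragm (SI) and chest (AP) amplitudes.  The liver fractions are calibrated
so the end-exhale -> end-inhale tumor excursion of the normal preset is
1.92 cm SI and 1.10 cm AP.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from importlib import resources

import numpy as np
import yaml

from .errors import InvalidArgumentError, InvalidConfigError

CATEGORIES = ("I", "II", "III", "IV")

#: id of the ambient-air "structure"; label 0 marks voxels outside the body.
AIR_ID = 0


@dataclass(frozen=True)
class StructureRecord:
    name: str
    id: int
    category: str
    base_A: float
    detail_B: float | None = None
    kappa_si: float = 0.0
    kappa_ap: float = 0.0

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise InvalidConfigError(f"unknown category {self.category!r}")
        has_b = self.detail_B is not None
        if self.category in ("I", "II") and not has_b:
            raise InvalidConfigError(f"{self.name}: categories I/II require a B value")
        if self.category in ("III", "IV") and has_b:
            raise InvalidConfigError(f"{self.name}: categories III/IV carry no B value")
        if not (0.0 <= self.kappa_si <= 1.0 and 0.0 <= self.kappa_ap <= 1.0):
            raise InvalidConfigError(f"{self.name}: motion fractions must lie in [0, 1]")
        if self.category == "IV" and (self.kappa_si or self.kappa_ap):
            raise InvalidConfigError(f"{self.name}: category IV structures carry zero kappa")


# name, id, category, A, B, kappa_si, kappa_ap
_DEFAULT_ROWS = [
    # category I — textured key organs
    ("liver",          15, "I", 95, 160, 0.96, 11.0 / 12.0),
    ("gallbladder",    16, "I", 82, 160, 0.96, 11.0 / 12.0),
    ("pancreas",       17, "I", 100, 112, 0.80, 0.60),
    ("spleen",         18, "I", 25, 170, 0.85, 0.60),
    ("stomach",        19, "I", 85, 140, 0.80, 0.60),
    ("kidneys",        20, "I", 90, 105, 0.75, 0.55),
    ("pericardium",    21, "I", 45, 150, 0.70, 0.40),
    ("myocardium",     22, "I", 65, 150, 0.70, 0.40),
    ("heart_blood",    23, "I", 110, 150, 0.70, 0.40),
    # category II — pattern-generated soft tissue
    ("muscle",          2, "II", 40, 140, 0.15, 0.30),
    ("body",            1, "II", 30, 80, 0.35, 0.30),
    ("static_marrow",   3, "II", 30, 80, 0.00, 0.00),
    ("intestine_wall",  4, "II", 30, 85, 0.55, 0.45),
    # category III — uniform (+ noise) air-dominated structures
    ("lungs",           5, "III", 18, None, 0.50, 0.40),
    ("airway_tree",     6, "III", 235, None, 0.45, 0.30),
    ("intestine_air",   7, "III", 40, None, 0.55, 0.45),
    ("esophagus_wall",  8, "III", 136, None, 0.40, 0.20),
    ("air",        AIR_ID, "III", 40, None, 0.00, 0.00),
    # category IV — bone, re-rendered per phase
    ("rib",             9, "IV", 32, None, 0.0, 0.0),
    ("spine",          10, "IV", 38, None, 0.0, 0.0),
    ("cord",           11, "IV", 195, None, 0.0, 0.0),
    ("cortical_bone",  12, "IV", 28, None, 0.0, 0.0),
    ("cartilage",      13, "IV", 140, None, 0.0, 0.0),
    ("mobile_marrow",  14, "IV", 135, None, 0.0, 0.0),
]

#: category-I organs mapped from the donor scan; heart subparts and the two
#: kidneys share one registration each, giving the 7 mapped organs.
MAPPED_ORGANS = (
    "liver", "gallbladder", "pancreas", "spleen", "stomach", "kidneys", "heart",
)
HEART_PARTS = ("pericardium", "myocardium", "heart_blood")
SPINE_COMPLEX = ("spine", "cord", "static_marrow")

#: chest-wall structures that ride with the anterior body-wall AP motion.
CHEST_WALL_BONES = ("rib", "cortical_bone", "cartilage", "mobile_marrow")

#: structures receiving additive Rayleigh noise.
NOISY_STRUCTURES = ("lungs", "intestine_air")


class StructureTable:
    """Registry of :class:`StructureRecord`, keyed by name and integer ID."""

    def __init__(self, records):
        self._by_name: dict[str, StructureRecord] = {}
        self._by_id: dict[int, StructureRecord] = {}
        for rec in records:
            if rec.name in self._by_name or rec.id in self._by_id:
                raise InvalidConfigError(f"duplicate structure {rec.name!r}/{rec.id}")
            self._by_name[rec.name] = rec
            self._by_id[rec.id] = rec

    def __iter__(self):
        return iter(self._by_name.values())

    def __len__(self):
        return len(self._by_name)

    def __contains__(self, key) -> bool:
        return key in self._by_name or key in self._by_id

    def __getitem__(self, key) -> StructureRecord:
        if isinstance(key, str):
            return self._by_name[key]
        return self._by_id[int(key)]

    @property
    def names(self) -> list[str]:
        return list(self._by_name)

    def of_category(self, category: str) -> list[StructureRecord]:
        return [r for r in self if r.category == category]

    def lookup_arrays(self):
        """(A, kappa_si, kappa_ap) dense lookup tables indexed by structure ID."""
        n = max(self._by_id) + 1
        base_a = np.zeros(n)
        ksi = np.zeros(n)
        kap = np.zeros(n)
        for rec in self:
            base_a[rec.id] = rec.base_A
            ksi[rec.id] = rec.kappa_si
            kap[rec.id] = rec.kappa_ap
        return base_a, ksi, kap

    # -- YAML round-trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        rows = [asdict(rec) for rec in self]
        with open(path, "w") as fh:
            yaml.safe_dump({"structures": rows}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StructureTable":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if not isinstance(payload, dict) or "structures" not in payload:
            raise InvalidConfigError(f"{path}: expected a 'structures' list")
        return cls([StructureRecord(**row) for row in payload["structures"]])

    @classmethod
    def default(cls) -> "StructureTable":
        return cls(
            StructureRecord(name, sid, cat, float(a),
                            None if b is None else float(b), ksi, kap)
            for name, sid, cat, a, b, ksi, kap in _DEFAULT_ROWS
        )

    @classmethod
    def from_package_data(cls) -> "StructureTable":
        """Load the shipped default table (data/structures.yaml)."""
        ref = resources.files("liverphantom").joinpath("data/structures.yaml")
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)


# ---------------------------------------------------------------------------
# respiratory motion–time curve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RespiratoryCurve:
    """Normalized amplitude fraction m(t) over one 5 s breathing cycle.

    m(0) = 0 at end of exhalation (EOE, the reference phase), m(2) = 1 at end
    of inhalation (EOI), back to 0 at t = 5 s; the inhale limb is
    sin^2(pi t / 4) and the slower exhale limb cos^2(pi (t - 2) / 6), giving a
    continuous periodic curve with the 2 s / 3 s asymmetry of quiet breathing.
    """

    cycle_s: float = 5.0
    t_eoi_s: float = 2.0

    def __call__(self, t):
        t = np.mod(np.asarray(t, dtype=float), self.cycle_s)
        inhale = np.sin(np.pi * t / (2.0 * self.t_eoi_s)) ** 2
        exhale = np.cos(np.pi * (t - self.t_eoi_s) / (2.0 * (self.cycle_s - self.t_eoi_s))) ** 2
        out = np.where(t < self.t_eoi_s, inhale, exhale)
        return float(out) if out.ndim == 0 else out


#: module-level default curve shared by the motion engine.
MOTION_CURVE = RespiratoryCurve()


def eval_motion_curve(t) -> float:
    """Amplitude fraction of the default 5 s curve at time ``t`` (seconds)."""
    return MOTION_CURVE(t)


def phase_times(n_phases: int = 10, cycle_s: float = 5.0) -> list[float]:
    """Uniform phase start times: 0, T/n, ..., (n-1) T/n."""
    if int(n_phases) < 1:
        raise InvalidArgumentError("n_phases must be >= 1")
    if not (cycle_s > 0):
        raise InvalidArgumentError("cycle must be positive")
    step = cycle_s / int(n_phases)
    return [p * step for p in range(int(n_phases))]


# ---------------------------------------------------------------------------
# breathing presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotionPreset:
    """Maximum diaphragm (SI) and chest (AP) amplitudes of one series, in cm."""

    name: str
    diaphragm_cm: float
    chest_ap_cm: float

    @property
    def diaphragm_mm(self) -> float:
        return self.diaphragm_cm * 10.0

    @property
    def chest_ap_mm(self) -> float:
        return self.chest_ap_cm * 10.0


PRESETS = {
    "large": MotionPreset("large", 3.0, 2.0),
    "normal": MotionPreset("normal", 2.0, 1.2),
    "limited": MotionPreset("limited", 2.0, 0.5),
}


def get_preset(name: str) -> MotionPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise InvalidConfigError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
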