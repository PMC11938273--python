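"""Synthetic feature tables mirroring the study database, plus toy molecules.

The reference dataset behind the permeability models is a table of 154
small molecules — 68 CNS-positive, 42 CNS-negative, 44 efflux-transporter
substrates/inhibitors — with 24 numeric features each.  This module
generates tables with that statistical shape so the whole pipeline runs
without any download:

* the 3D PSA column uses the per-class parameters reported for the real
  data — normal(62.9, 34.7) Å² for CNS-positive, normal(146.2, 94.4) for
  CNS-negative, normal(149.6, 68.6) for efflux, truncated at 0 (areas are
  non-negative).  CNS-negative and efflux deliberately overlap, so that
  pair is genuinely hard, as in the real data;
* the remaining 23 features have no published per-class statistics; they
  default to unit-variance normals (standardized units) whose class means
  are shifted by a configurable effect size (default 1 SD) in a rotating
  pattern, so each pair of classes is separated by several features —
  a strongly learnable, but not trivial, signal.

Also packaged: five small molecules (methane, water, ethanol, benzene,
glycine) with frozen force-field-minimized coordinates, used as geometry
fixtures throughout the test-suite and docs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .features import ALLOWED_LABELS, FeatureTable
from .molio import Atom, Molecule3D

__all__ = [
    "FEATURE_NAMES",
    "ClassSpec",
    "GeneratorConfig",
    "default_config",
    "generate_feature_table",
    "recover_group_parameters",
    "fixture_molecules",
]

FEATURE_NAMES: tuple[str, ...] = (
    "psa3d", "psa_acd", "tpsa", "mw", "hbd", "hba", "rotatable_bonds",
    "aromatic_rings", "heavy_atoms", "mwhbn", "pka_basic", "clogp",
    "clogd_74", "hplc_logp_74", "kiam", "pm", "pct_hsa", "logk",
    "hba_plus_hbd", "logp_minus_hba", "logd74_minus_hba",
    "hplclogp74_minus_hba", "bbb_score", "cns_mpo",
)

# Reported per-class 3D PSA parameters (mean, SD) in Å²
PSA3D_PARAMS = {"cns_pos": (62.9, 34.7), "cns_neg": (146.2, 94.4), "efflux": (149.6, 68.6)}
CLASS_SIZES = {"cns_pos": 68, "cns_neg": 42, "efflux": 44}

# rotating class-offset patterns (cns_pos, cns_neg, efflux) in SD units;
# every class pair differs on ~2/3 of the features
_OFFSET_PATTERNS = ((0.0, 1.0, 1.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0), (0.0, 0.5, 1.0))


@dataclass(frozen=True)
class ClassSpec:
    """One class: its label, size and per-feature normal parameters."""

    label: str
    n: int
    feature_params: dict[str, tuple[float, float]]  # name -> (mean, sd)
    floors: dict[str, float] = field(default_factory=dict)  # truncation floors

    def __post_init__(self) -> None:
        if self.label not in ALLOWED_LABELS:
            raise ConfigurationError(f"unknown label {self.label!r}")
        if self.n < 2:
            raise ConfigurationError("class size must be >= 2")
        for name, (_, sd) in self.feature_params.items():
            if sd < 0:
                raise ConfigurationError(f"negative SD for {name!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full generator configuration (defaults = the study conditions)."""

    class_specs: tuple[ClassSpec, ...]
    correlation: float = 0.0  # equicorrelation across features
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.correlation <= 0.95:
            raise ConfigurationError("correlation must be in [0, 0.95]")
        if not 0.0 <= self.missing_rate <= 0.5:
            raise ConfigurationError("missing_rate must be in [0, 0.5]")
        names = {tuple(sorted(cs.feature_params)) for cs in self.class_specs}
        if len(names) != 1:
            raise ConfigurationError("all classes must share the same feature set")

    @property
    def feature_names(self) -> list[str]:
        return sorted(self.class_specs[0].feature_params)


def default_config(
    effect_size: float = 1.0,
    correlation: float = 0.0,
    missing_rate: float = 0.0,
    class_sizes: dict[str, int] | None = None,
) -> GeneratorConfig:
    """The packaged defaults: 68/42/44 classes, reported 3D PSA parameters,
    and rotating ``effect_size``-SD shifts on the other 23 features."""
    sizes = dict(CLASS_SIZES)
    if class_sizes:
        sizes.update(class_sizes)
    specs = []
    for label in ALLOWED_LABELS:
        class_idx = ALLOWED_LABELS.index(label)
        params: dict[str, tuple[float, float]] = {"psa3d": PSA3D_PARAMS[label]}
        for j, name in enumerate(n for n in FEATURE_NAMES if n != "psa3d"):
            pattern = _OFFSET_PATTERNS[j % len(_OFFSET_PATTERNS)]
            params[name] = (effect_size * pattern[class_idx], 1.0)
        specs.append(
            ClassSpec(label=label, n=sizes[label], feature_params=params, floors={"psa3d": 0.0})
        )
    return GeneratorConfig(
        class_specs=tuple(specs), correlation=correlation, missing_rate=missing_rate
    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, floor: float, size: int
) -> np.ndarray:
    """Rejection-sample normal(mean, sd) conditioned on >= floor."""
    out = rng.normal(mean, sd, size=size)
    for _ in range(1000):
        bad = out < floor
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise ConfigurationError(
        f"truncation floor {floor} is unreachable for normal({mean}, {sd})"
    )


def generate_feature_table(
    config: GeneratorConfig | None = None, seed: int = 0
) -> FeatureTable:
    """Draw one synthetic feature table; identical (config, seed) pairs
    produce bitwise-identical tables."""
    config = config or default_config()
    rng = np.random.default_rng(seed)
    names = config.feature_names
    rho = config.correlation
    rows, labels = [], []
    for spec in config.class_specs:
        shared = rng.standard_normal((spec.n, 1)) if rho > 0 else 0.0
        block = np.empty((spec.n, len(names)))
        for j, name in enumerate(names):
            mean, sd = spec.feature_params[name]
            floor = spec.floors.get(name)
            if rho > 0:
                z = np.sqrt(rho) * shared[:, 0] + np.sqrt(1 - rho) * rng.standard_normal(spec.n)
                col = mean + sd * z
                if floor is not None:
                    clipped = col < floor  # re-draw independently below the floor
                    if clipped.any():
                        col[clipped] = _truncated_normal(rng, mean, sd, floor, int(clipped.sum()))
            elif floor is not None:
                col = _truncated_normal(rng, mean, sd, floor, spec.n)
            else:
                col = rng.normal(mean, sd, size=spec.n)
            block[:, j] = col
        rows.append(block)
        labels += [spec.label] * spec.n
    X = np.vstack(rows)
    if config.missing_rate > 0:
        mask = rng.random(X.shape) < config.missing_rate
        X = np.where(mask, np.nan, X)
    ids = [f"mol_{i:04d}" for i in range(len(X))]
    df = pd.DataFrame(X, columns=names, index=pd.Index(ids, name="id"))
    df["label"] = labels
    return FeatureTable(data=df)


def recover_group_parameters(table: FeatureTable, feature: str) -> dict[str, dict[str, float]]:
    """Per-class sample mean/SD/n of one feature (parameter-recovery check)."""
    out = {}
    for label, group in table.data.groupby(table.labels):
        vals = group[feature].dropna()
        out[str(label)] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)),
            "n": int(len(group)),
        }
    return out


# ---------------------------------------------------------------------------
# Fixture molecules (frozen MMFF94-minimized geometries, Å)


_FIXTURES: dict[str, tuple[list[tuple[str, tuple[float, float, float]]], list[tuple[int, int, float]]]] = {
    "methane": (
        [
            ("C", (0.0000, -0.0000, -0.0000)),
            ("H", (0.5325, 0.7502, -0.5887)),
            ("H", (0.7181, -0.5883, 0.5753)),
            ("H", (-0.5577, -0.6591, -0.6689)),
            ("H", (-0.6929, 0.4973, 0.6823)),
        ],
        [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0), (0, 4, 1.0)],
    ),
    "water": (
        [
            ("O", (-0.0003, 0.3978, 0.0000)),
            ("H", (-0.7633, -0.1996, 0.0000)),
            ("H", (0.7636, -0.1983, 0.0000)),
        ],
        [(0, 1, 1.0), (0, 2, 1.0)],
    ),
    "ethanol": (
        [
            ("C", (0.9026, -0.0500, 0.0214)),
            ("C", (-0.5742, -0.3855, 0.0406)),
            ("O", (-1.3316, 0.7757, 0.3485)),
            ("H", (1.2173, 0.3593, 0.9870)),
            ("H", (1.1162, 0.7142, -0.7332)),
            ("H", (1.5015, -0.9383, -0.1982)),
            ("H", (-0.7850, -1.1421, 0.8019)),
            ("H", (-0.9017, -0.7714, -0.9295)),
            ("H", (-1.1450, 1.4381, -0.3385)),
        ],
        [(0, 1, 1.0), (0, 3, 1.0), (0, 4, 1.0), (0, 5, 1.0), (1, 2, 1.0),
         (1, 6, 1.0), (1, 7, 1.0), (2, 8, 1.0)],
    ),
    "benzene": (
        [
            ("C", (-1.2473, 0.6241, -0.0130)),
            ("C", (-1.1643, -0.7677, 0.0260)),
            ("C", (0.0831, -1.3918, 0.0391)),
            ("C", (1.2473, -0.6241, 0.0130)),
            ("C", (1.1643, 0.7677, -0.0260)),
            ("C", (-0.0831, 1.3918, -0.0391)),
            ("H", (-2.2191, 1.1104, -0.0232)),
            ("H", (-2.0714, -1.3658, 0.0463)),
            ("H", (0.1478, -2.4762, 0.0695)),
            ("H", (2.2191, -1.1104, 0.0232)),
            ("H", (2.0714, 1.3658, -0.0463)),
            ("H", (-0.1478, 2.4762, -0.0695)),
        ],
        [(0, 1, 1.5), (0, 5, 1.5), (0, 6, 1.0), (1, 2, 1.5), (1, 7, 1.0),
         (2, 3, 1.5), (2, 8, 1.0), (3, 4, 1.5), (3, 9, 1.0), (4, 5, 1.5),
         (4, 10, 1.0), (5, 11, 1.0)],
    ),
    "glycine": (
        [
            ("N", (-1.4693, 0.4070, -0.1983)),
            ("C", (-0.5424, -0.7191, 0.0371)),
            ("C", (0.9076, -0.2639, 0.1540)),
            ("O", (1.8521, -0.9626, 0.4858)),
            ("O", (1.1067, 1.0321, -0.1734)),
            ("H", (-1.1094, 0.9351, -0.9973)),
            ("H", (-1.3765, 1.0586, 0.5828)),
            ("H", (-0.6162, -1.4216, -0.7976)),
            ("H", (-0.8255, -1.2199, 0.9671)),
            ("H", (2.0730, 1.1542, -0.0604)),
        ],
        [(0, 1, 1.0), (0, 5, 1.0), (0, 6, 1.0), (1, 2, 1.0), (1, 7, 1.0),
         (1, 8, 1.0), (2, 3, 2.0), (2, 4, 1.0), (4, 9, 1.0)],
    ),
}


def fixture_molecules() -> dict[str, Molecule3D]:
    """Five packaged molecules with frozen minimized coordinates."""
    out = {}
    for name, (atoms, bonds) in _FIXTURES.items():
        out[name] = Molecule3D(
            id=name,
            atoms=[Atom(element=el, position=np.array(pos)) for el, pos in atoms],
            bonds=[tuple(b) for b in bonds],
            provenance="optimized",
        )
    return out
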