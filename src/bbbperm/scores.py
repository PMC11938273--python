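"""2D descriptors and multiparameter desirability scores.

Descriptors (molecular weight, tPSA, hydrogen-bond counts, rotatable bonds,
...) are computed with RDKit; tPSA is the Ertl fragment-sum approximation
(RDKit's packaged fragment table).  Multiparameter scores — the BBB score,
CNS MPO, and CNS MPO PET — are weighted sums of piecewise-linear
desirability functions of those descriptors, with CNS-positivity cutoffs of
4, 4 and 3 respectively.  The knot tables ship as editable YAML configs; the
machinery (interpolation, clamping, weighting, thresholding) lives here.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem
from rdkit.Chem import Descriptors, Lipinski, rdMolDescriptors

from .exceptions import ConfigurationError, MissingFeatureError, ParseError
from .molio import Molecule3D, to_rdkit

__all__ = [
    "PiecewiseDesirability",
    "ScoreComponent",
    "ScoreDefinition",
    "eval_desirability",
    "compute_score",
    "classify_score",
    "compute_tpsa",
    "compute_counts",
    "derive_combos",
    "load_score_definition",
    "available_scores",
    "score_table",
]

logger = logging.getLogger(__name__)

CNS_POSITIVE = "cns_pos"
CNS_NEGATIVE = "cns_neg"


@dataclass(frozen=True)
class PiecewiseDesirability:
    """A piecewise-linear desirability curve: knots (strictly increasing x)
    mapped to values in [0, 1], clamped to the terminal values outside."""

    knots: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "knots", tuple(float(k) for k in self.knots))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.knots) < 2 or len(self.knots) != len(self.values):
            raise ConfigurationError("need >= 2 knots with matching values")
        if any(b <= a for a, b in zip(self.knots, self.knots[1:])):
            raise ConfigurationError("knots must be strictly increasing")
        if any(not 0.0 <= v <= 1.0 for v in self.values):
            raise ConfigurationError("desirability values must lie in [0, 1]")

    def __call__(self, x: float) -> float:
        return eval_desirability(self, x)


def eval_desirability(d: PiecewiseDesirability, x: float) -> float:
    """Linear interpolation between bracketing knots; clamped outside."""
    if not math.isfinite(x):
        raise ValueError(f"desirability input must be finite, got {x!r}")
    return float(np.interp(x, d.knots, d.values))


@dataclass(frozen=True)
class ScoreComponent:
    descriptor: str
    weight: float
    desirability: PiecewiseDesirability

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ConfigurationError("component weight must be >= 0")


@dataclass(frozen=True)
class ScoreDefinition:
    """A named weighted sum of desirability components with a CNS cutoff.

    The score ranges over [0, sum of weights]; a molecule scoring at or
    above ``threshold`` is classified ``positive_label``.
    """

    name: str
    components: tuple[ScoreComponent, ...]
    threshold: float
    positive_label: str = CNS_POSITIVE
    negative_label: str = CNS_NEGATIVE

    @property
    def max_score(self) -> float:
        return sum(c.weight for c in self.components)


def compute_score(definition: ScoreDefinition, descriptors: Mapping[str, float]) -> float:
    """Σ weight·desirability(descriptor value); lies in [0, Σ weights]."""
    total = 0.0
    for comp in definition.components:
        if comp.descriptor not in descriptors or pd.isna(descriptors[comp.descriptor]):
            raise MissingFeatureError(
                f"score {definition.name!r} needs descriptor {comp.descriptor!r}"
            )
        total += comp.weight * eval_desirability(comp.desirability, float(descriptors[comp.descriptor]))
    return total


def classify_score(definition: ScoreDefinition, score: float) -> str:
    """CNS-positive iff score >= threshold (boundary counts as positive)."""
    if not math.isfinite(score):
        raise ValueError("score must be finite")
    return definition.positive_label if score >= definition.threshold else definition.negative_label


# ---------------------------------------------------------------------------
# Descriptors


def compute_tpsa(molecule: Molecule3D | Chem.Mol, include_s_and_p: bool = False) -> float:
    """Topological PSA: Ertl fragment contributions summed over matched
    N/O (optionally S/P) environments.  Purely 2D and deterministic."""
    mol = molecule if isinstance(molecule, Chem.Mol) else to_rdkit(molecule)
    return float(rdMolDescriptors.CalcTPSA(mol, includeSandP=include_s_and_p))


def compute_counts(molecule: Molecule3D | Chem.Mol) -> dict[str, float]:
    """Count/weight descriptors: mw, hbd, hba, rotatable_bonds,
    aromatic_rings, heavy_atoms, tpsa and mwhbn = (hbd+hba)/sqrt(mw).

    Donors are N/O bearing at least one hydrogen; acceptors follow the
    Lipinski N+O convention; rotatable bonds are non-ring single bonds
    between non-terminal heavy atoms with amide C–N excluded.
    """
    mol = molecule if isinstance(molecule, Chem.Mol) else to_rdkit(molecule)
    mw = float(Descriptors.MolWt(mol))
    hbd = sum(
        1
        for a in mol.GetAtoms()
        if a.GetSymbol() in ("N", "O") and a.GetTotalNumHs(includeNeighbors=True) >= 1
    )
    hba = int(Lipinski.NOCount(mol))
    return {
        "mw": mw,
        "hbd": hbd,
        "hba": hba,
        # strict SMARTS excludes terminal atoms by degree, so count on the
        # hydrogen-suppressed graph
        "rotatable_bonds": int(rdMolDescriptors.CalcNumRotatableBonds(Chem.RemoveHs(mol))),
        "aromatic_rings": int(rdMolDescriptors.CalcNumAromaticRings(mol)),
        "heavy_atoms": int(mol.GetNumHeavyAtoms()),
        "tpsa": compute_tpsa(mol),
        "mwhbn": (hbd + hba) / math.sqrt(mw) if mw > 0 else float("nan"),
    }


_COMBOS = {
    "hba_plus_hbd": ("hba", "hbd", "+"),
    "logp_minus_hba": ("clogp", "hba", "-"),
    "logd74_minus_hba": ("clogd_74", "hba", "-"),
    "hplclogp74_minus_hba": ("hplc_logp_74", "hba", "-"),
}


def derive_combos(descriptors: Mapping[str, float]) -> dict[str, float]:
    """Add the derived combination columns (HBA+HBD, logP−HBA, logD−HBA,
    HPLC logP−HBA).  A missing operand yields a missing result (NaN)."""
    out = dict(descriptors)
    for name, (a, b, op) in _COMBOS.items():
        va, vb = out.get(a), out.get(b)
        if va is None or vb is None or pd.isna(va) or pd.isna(vb):
            out[name] = float("nan")
        else:
            out[name] = va + vb if op == "+" else va - vb
    return out


# ---------------------------------------------------------------------------
# Score config loading


def _definition_from_dict(cfg: dict) -> ScoreDefinition:
    try:
        components = tuple(
            ScoreComponent(
                descriptor=c["descriptor"],
                weight=float(c["weight"]),
                desirability=PiecewiseDesirability(tuple(c["knots"]), tuple(c["values"])),
            )
            for c in cfg["components"]
        )
        return ScoreDefinition(
            name=cfg["name"], components=components, threshold=float(cfg["threshold"])
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed score definition: {exc}") from exc


def available_scores() -> list[str]:
    root = importlib.resources.files("bbbperm.data.scores")
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_score_definition(name_or_path: str) -> ScoreDefinition:
    """Load a packaged score by name (``bbb_score``, ``cns_mpo``,
    ``cns_mpo_pet``) or any YAML file by path."""
    root = importlib.resources.files("bbbperm.data.scores")
    packaged = root / f"{name_or_path}.yaml"
    if packaged.is_file():
        cfg = yaml.safe_load(packaged.read_text())
    else:
        try:
            with open(name_or_path, encoding="utf-8") as fh:
                cfg = yaml.safe_load(fh)
        except FileNotFoundError:
            raise ConfigurationError(
                f"unknown score {name_or_path!r}; packaged: {', '.join(available_scores())}"
            ) from None
    return _definition_from_dict(cfg)


def score_table(
    table: pd.DataFrame, definition: ScoreDefinition, out_column: str | None = None
) -> pd.DataFrame:
    """Append a score column (and ``<score>_class``) to a feature table."""
    out_column = out_column or definition.name
    scores, labels = [], []
    for _, row in table.iterrows():
        s = compute_score(definition, row)
        scores.append(s)
        labels.append(classify_score(definition, s))
    out = table.copy()
    out[out_column] = scores
    out[f"{out_column}_class"] = labels
    return out
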