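"""Property scorers, orientation transforms, and the raw metric vector ``h``.

An :class:`ObjectiveSet` defines the layout of the metric vector the
search optimizes: an ordered list of named objectives, each with a
direction.  Before entering dominance comparisons every raw metric is
*oriented* so that larger is better — minimize-type metrics (the
synthetic-accessibility score) are negated, and range-type metrics
become {0, 1} window indicators.  Reported outputs undo the transform.

Chemistry scorers wrap the standard RDKit implementations: Wildman-
Crippen LogP, QED drug-likeness, the Ertl-Schuffenhauer synthetic
accessibility score, and the Ertl natural-product likeness score (the
latter two from the RDKit contrib tree).  Docking through an external
``smina`` executable is optional and activates only with an explicit
receptor + executable configuration.  Token-count surrogate objectives
support full-pipeline tests with no chemistry at all.
"""

from __future__ import annotations

import os
import re
import shutil
import subprocess
import sys
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .policy import TERMINAL

__all__ = [
    "InvalidMoleculeError",
    "ConfigurationError",
    "ObjectiveSpec",
    "ObjectiveSet",
    "logp_range_metric",
    "score_properties",
    "canonical_smiles",
    "toy_canonicalizer",
    "surrogate_objective",
    "drug_likeness_objectives",
    "toy_objectives",
    "DockingConfig",
    "SminaDocking",
    "descriptor_versions",
    "LOGP_WINDOW",
]

#: Druggable LogP window (Ghose filter), boundaries inclusive.
LOGP_WINDOW = (-0.4, 5.6)


class InvalidMoleculeError(ValueError):
    """The token string does not parse/canonicalize as a molecule."""


class ConfigurationError(RuntimeError):
    """An external resource (executable, receptor file) is missing or unusable."""


def logp_range_metric(logp: float, lo: float = LOGP_WINDOW[0], hi: float = LOGP_WINDOW[1]) -> int:
    """Window indicator: 1 iff ``lo <= logp <= hi`` (boundaries inclusive)."""
    if not np.isfinite(logp):
        raise ValueError(f"logp must be finite, got {logp!r}")
    return int(lo <= logp <= hi)


# -- RDKit descriptor plumbing -------------------------------------------

_sascorer = None
_npscorer = None
_np_model = None


def _contrib_scorers():
    """Import the SA and NP contrib scorers once, extending sys.path as needed."""
    global _sascorer, _npscorer, _np_model
    if _sascorer is None:
        from rdkit import RDConfig

        for sub in ("SA_Score", "NP_Score"):
            p = os.path.join(RDConfig.RDContribDir, sub)
            if p not in sys.path:
                sys.path.append(p)
        import sascorer  # type: ignore
        import npscorer  # type: ignore

        _sascorer = sascorer
        _npscorer = npscorer
        _np_model = npscorer.readNPModel()
    return _sascorer, _npscorer, _np_model


def _mol_from_text(molecule: str):
    from rdkit import Chem

    text = molecule.rstrip(TERMINAL)
    if not text:
        raise InvalidMoleculeError("empty molecule string")
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise InvalidMoleculeError(f"unparsable SMILES: {text!r}")
    return mol


def canonical_smiles(molecule: str) -> str:
    """Canonical SMILES of ``molecule`` (terminal symbol stripped first).

    Raises :class:`InvalidMoleculeError` when RDKit cannot parse the text.
    """
    from rdkit import Chem

    return Chem.MolToSmiles(_mol_from_text(molecule))


def score_properties(molecule: str) -> dict[str, float]:
    """Standard descriptor panel for a molecule given as (tokenized) SMILES.

    Returns ``{"logp", "qed", "sa", "np"}``: Wildman-Crippen LogP, QED
    in [0, 1], synthetic accessibility in [1, 10] (1 = easy to make),
    and natural-product likeness in roughly [-5, 5].  Deterministic:
    the same input always yields the same values.
    """
    from rdkit.Chem import Crippen, QED

    mol = _mol_from_text(molecule)
    sascorer, npscorer, np_model = _contrib_scorers()
    return {
        "logp": float(Crippen.MolLogP(mol)),
        "qed": float(QED.qed(mol)),
        "sa": float(sascorer.calculateScore(mol)),
        "np": float(npscorer.scoreMol(mol, np_model)),
    }


def descriptor_versions() -> dict[str, str]:
    """Version metadata for the descriptor implementations, for run logs."""
    import rdkit

    return {"rdkit": rdkit.__version__}


def toy_canonicalizer(molecule: str) -> str:
    """Canonical form of a toy token string: itself, iff properly terminated."""
    if not molecule or not molecule.endswith(TERMINAL):
        raise InvalidMoleculeError(f"toy molecule not terminated: {molecule!r}")
    return molecule


# -- objective specification ---------------------------------------------


@dataclass(frozen=True)
class ObjectiveSpec:
    """One named objective: a scorer plus its optimization direction.

    ``direction`` is ``"maximize"``, ``"minimize"`` or ``"range"``; a
    range objective carries inclusive ``bounds = (lo, hi)`` and its
    oriented value is the window indicator.
    """

    name: str
    scorer: Callable[[str], float]
    direction: str = "maximize"
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("maximize", "minimize", "range"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.direction == "range":
            if self.bounds is None or not self.bounds[0] < self.bounds[1]:
                raise ValueError("range objective requires bounds with lo < hi")

    def orient(self, raw: float) -> float:
        """Transform a raw score so that larger is better."""
        if self.direction == "minimize":
            return -raw
        if self.direction == "range":
            return float(logp_range_metric(raw, *self.bounds))
        return raw

    def unorient(self, oriented: float) -> float:
        """Undo :meth:`orient` for reporting (range indicators stay in {0,1})."""
        if self.direction == "minimize":
            return -oriented
        return oriented


class ObjectiveSet:
    """Ordered objectives defining the dimension and layout of ``h``.

    ``canonicalize`` maps a rollout token string to the canonical
    molecule text used for deduplication (and raises
    :class:`InvalidMoleculeError` for chemically invalid strings).
    """

    def __init__(
        self,
        specs: Sequence[ObjectiveSpec],
        canonicalize: Callable[[str], str] = toy_canonicalizer,
    ):
        specs = tuple(specs)
        if not specs:
            raise ValueError("ObjectiveSet requires at least one objective")
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError(f"objective names must be unique: {names}")
        self.specs = specs
        self.canonicalize = canonicalize

    @property
    def dim(self) -> int:
        return len(self.specs)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    def raw_scores(self, molecule: str) -> dict[str, float]:
        """Raw (un-oriented) metric values, keyed by objective name."""
        out = {}
        for spec in self.specs:
            try:
                out[spec.name] = float(spec.scorer(molecule))
            except InvalidMoleculeError:
                raise
            except Exception as exc:
                raise InvalidMoleculeError(
                    f"scorer {spec.name!r} failed on {molecule!r}: {exc}"
                ) from exc
        return out

    def assemble_h(self, molecule: str) -> np.ndarray:
        """Oriented metric vector of ``molecule`` in objective order."""
        raw = self.raw_scores(molecule)
        return np.array([spec.orient(raw[spec.name]) for spec in self.specs])

    def unorient(self, h: Iterable[float]) -> dict[str, float]:
        """Map an oriented ``h`` back to raw reporting scale, keyed by name."""
        h = np.asarray(h, float)
        if h.size != self.dim:
            raise ValueError(f"dimension mismatch: {h.size} vs {self.dim}")
        return {spec.name: spec.unorient(v) for spec, v in zip(self.specs, h)}


# -- surrogate (token-count) objectives ----------------------------------

_TERM_RE = re.compile(r"^(count(?P<tok>.)|length)$")


def surrogate_objective(expr: str) -> Callable[[str], float]:
    """Deterministic scorer over token counts and length.

    ``expr`` is a ±-separated combination of terms ``count<token>`` and
    ``length``, e.g. ``"countA"``, ``"length"``, ``"countA - countB"``.
    Enables full-pipeline tests with no chemistry or external binaries.
    """
    signed: list[tuple[int, str]] = []
    rest = expr.replace(" ", "")
    sign = 1
    while rest:
        m = re.match(r"(count.|length)", rest)
        if not m:
            raise ValueError(f"cannot parse surrogate expression {expr!r}")
        signed.append((sign, m.group(1)))
        rest = rest[m.end():]
        if rest:
            if rest[0] == "+":
                sign = 1
            elif rest[0] == "-":
                sign = -1
            else:
                raise ValueError(f"cannot parse surrogate expression {expr!r}")
            rest = rest[1:]

    def scorer(molecule: str) -> float:
        total = 0.0
        for s, term in signed:
            if term == "length":
                total += s * len(molecule)
            else:
                total += s * molecule.count(term[5])
        return total

    scorer.__name__ = f"surrogate_{expr}"
    return scorer


# -- ready-made objective sets -------------------------------------------


def drug_likeness_objectives(include: Sequence[str] = ("qed", "sa", "np", "logp_range")) -> ObjectiveSet:
    """The default download-free chemistry objective set.

    Components: QED (maximize), SA score (minimize), NP-likeness
    (maximize), and the LogP window indicator on [-0.4, 5.6].  Docking
    is added separately via :class:`SminaDocking` when a receptor and
    executable are configured.
    """
    catalog = {
        "qed": ObjectiveSpec("qed", lambda m: score_properties(m)["qed"], "maximize"),
        "sa": ObjectiveSpec("sa", lambda m: score_properties(m)["sa"], "minimize"),
        "np": ObjectiveSpec("np", lambda m: score_properties(m)["np"], "maximize"),
        "logp_range": ObjectiveSpec(
            "logp_range", lambda m: score_properties(m)["logp"], "range", LOGP_WINDOW
        ),
    }
    try:
        specs = [catalog[name] for name in include]
    except KeyError as exc:
        raise ValueError(f"unknown chemistry objective {exc.args[0]!r}") from exc
    return ObjectiveSet(specs, canonicalize=canonical_smiles)


def toy_objectives(exprs: Sequence[str], directions: Sequence[str] | None = None) -> ObjectiveSet:
    """Surrogate objective set over token-count expressions."""
    if directions is None:
        directions = ["maximize"] * len(exprs)
    specs = [
        ObjectiveSpec(expr.replace(" ", ""), surrogate_objective(expr), direction)
        for expr, direction in zip(exprs, directions)
    ]
    return ObjectiveSet(specs, canonicalize=toy_canonicalizer)


# -- docking adapter -----------------------------------------------------


@dataclass(frozen=True)
class DockingConfig:
    """Configuration for the external docking executable.

    ``autobox_ligand`` defines the search box around a reference ligand
    file; every parameter passed is recorded in run logs.
    """

    executable: str
    receptor: str
    autobox_ligand: str | None = None
    exhaustiveness: int = 8
    extra_args: tuple[str, ...] = ()


class SminaDocking:
    """Score molecules by docking against a receptor with smina/vina.

    The oriented objective value is the *negated* best binding energy
    (kcal/mol), so higher means stronger predicted binding.  Setup
    fails immediately — not mid-search — when the executable or
    receptor is missing.
    """

    def __init__(self, config: DockingConfig):
        exe = shutil.which(config.executable) or (
            config.executable if Path(config.executable).is_file() else None
        )
        if exe is None:
            raise ConfigurationError(f"docking executable not found: {config.executable!r}")
        if not Path(config.receptor).is_file():
            raise ConfigurationError(f"receptor file not found: {config.receptor!r}")
        self.config = config
        self.executable = exe

    def spec(self, name: str = "docking") -> ObjectiveSpec:
        # raw value = binding energy; minimize orientation performs the negation
        return ObjectiveSpec(name, self.binding_energy, "minimize")

    def binding_energy(self, molecule: str) -> float:
        """Best (lowest) smina affinity for ``molecule``; failures are invalid-molecule."""
        from rdkit import Chem
        from rdkit.Chem import AllChem

        mol = _mol_from_text(molecule)
        mol = Chem.AddHs(mol)
        if AllChem.EmbedMolecule(mol, randomSeed=0xF00D) != 0:
            raise InvalidMoleculeError(f"3D embedding failed for {molecule!r}")
        AllChem.MMFFOptimizeMolecule(mol)
        with tempfile.TemporaryDirectory() as tmp:
            ligand = Path(tmp) / "ligand.sdf"
            Chem.SDWriter(str(ligand)).write(mol)
            cmd = [self.executable, "-r", self.config.receptor, "-l", str(ligand),
                   "--exhaustiveness", str(self.config.exhaustiveness),
                   "--out", str(Path(tmp) / "out.sdf")]
            if self.config.autobox_ligand:
                cmd += ["--autobox_ligand", self.config.autobox_ligand]
            cmd += list(self.config.extra_args)
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise InvalidMoleculeError(
                    f"docking failed for {molecule!r}: {proc.stderr.strip()[:300]}"
                )
            energies = [
                float(m.group(1))
                for m in re.finditer(r"^\s*\d+\s+(-?\d+\.\d+)", proc.stdout, re.M)
            ]
            if not energies:
                raise InvalidMoleculeError(f"no docking poses for {molecule!r}")
            return min(energies)
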