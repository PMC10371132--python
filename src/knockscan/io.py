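"""Model and medium I/O plus medium application.

Genome-scale models are read and written through COBRApy in the two standard
interchange formats (SBML Level 3 + FBC, BiGG-style JSON).  A medium is a
mapping from exchange-reaction ids to maximum uptake rates
(mmol gDW^-1 h^-1, non-negative magnitudes); applying it sets exchange lower
bounds following the usual sign convention (negative flux = uptake, positive
= secretion).  Exchanges absent from the medium have their uptake closed while
secretion stays open — minimal-medium semantics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import cobra
import cobra.io
import yaml
from cobra import Model

from .errors import ConfigurationError, FormatError

_SBML_SUFFIXES = {".xml", ".sbml"}
_JSON_SUFFIXES = {".json"}


def _detect_format(path: Path) -> str:
    if path.suffix.lower() in _SBML_SUFFIXES:
        return "sbml-fbc"
    if path.suffix.lower() in _JSON_SUFFIXES:
        return "bigg-json"
    raise FormatError(
        f"cannot infer model format from suffix {path.suffix!r}; pass format explicitly"
    )


def load_model(path: Union[str, Path], format: Optional[str] = None) -> Model:
    """Load a metabolic model from SBML+FBC or BiGG-style JSON.

    Reversibility is encoded purely through a negative lower bound; reactions
    are never split.  The model must declare an objective reaction.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"model file not found: {path}")
    fmt = format or _detect_format(path)
    try:
        if fmt == "sbml-fbc":
            model = cobra.io.read_sbml_model(str(path))
        elif fmt == "bigg-json":
            model = cobra.io.load_json_model(str(path))
        else:
            raise FormatError(f"unknown model format {fmt!r}")
    except FormatError:
        raise
    except Exception as exc:  # parser errors vary by backend
        raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    if not any(r.objective_coefficient for r in model.reactions):
        raise ConfigurationError(f"model {path} declares no objective reaction")
    return model


def save_model(model: Model, path: Union[str, Path], format: Optional[str] = None) -> None:
    """Serialize a model to SBML+FBC or BiGG-style JSON (by suffix if omitted)."""
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt == "sbml-fbc":
        cobra.io.write_sbml_model(model, str(path))
    elif fmt == "bigg-json":
        cobra.io.save_json_model(model, str(path))
    else:
        raise FormatError(f"unknown model format {fmt!r}")


def exchange_reactions(model: Model) -> list:
    """Boundary reactions that exchange matter with the environment.

    BiGG convention: boundary reactions whose id starts with ``EX_``.  If a
    model uses no such prefix, fall back to COBRApy's exchange detection.
    Demand/sink reactions (including single-metabolite biomass drains of toy
    models) are deliberately excluded — they are not medium controls.
    """
    prefixed = [r for r in model.boundary if r.id.upper().startswith("EX_")]
    if prefixed:
        return prefixed
    return list(model.exchanges)


@dataclass(frozen=True)
class MediumSpec:
    """Exchange uptake limits; unlisted exchanges get ``default_uptake`` (0)."""

    uptakes: Mapping[str, float] = field(default_factory=dict)
    default_uptake: float = 0.0

    def __post_init__(self):
        for rid, rate in self.uptakes.items():
            if rate < 0:
                raise ConfigurationError(
                    f"uptake rate for {rid!r} must be a non-negative magnitude, got {rate}"
                )


def read_medium(path: Union[str, Path]) -> MediumSpec:
    """Read a medium from 2-column TSV (exchange_id, max_uptake) or YAML."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"YAML medium {path} must be a mapping")
        default = float(data.pop("default_uptake", 0.0))
        return MediumSpec({str(k): float(v) for k, v in data.items()}, default)
    uptakes: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'exchange_id<TAB>max_uptake'")
            try:
                uptakes[parts[0]] = float(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad uptake value {parts[1]!r}") from exc
    return MediumSpec(uptakes)


def apply_medium(model: Model, medium: MediumSpec) -> Model:
    """Return a copy of ``model`` constrained to the given medium.

    Listed exchanges get ``lb = -max_uptake``; every other exchange gets
    ``lb = -default_uptake`` (0 by default, i.e. uptake closed).  Upper bounds
    and non-exchange reactions are untouched, so secretion stays open and the
    operation is idempotent.
    """
    new = model.copy()
    ex = {r.id: r for r in exchange_reactions(new)}
    for rid in medium.uptakes:
        if rid not in ex:
            raise ConfigurationError(f"medium references unknown exchange {rid!r}")
    for rid, rxn in ex.items():
        rxn.lower_bound = -float(medium.uptakes.get(rid, medium.default_uptake))
    return new


def models_equal(a: Model, b: Model) -> bool:
    """Field-by-field equality of two models (ids, stoichiometry, bounds, GPRs)."""
    if sorted(m.id for m in a.metabolites) != sorted(m.id for m in b.metabolites):
        return False
    if sorted(r.id for r in a.reactions) != sorted(r.id for r in b.reactions):
        return False
    for ra in a.reactions:
        rb = b.reactions.get_by_id(ra.id)
        if (ra.lower_bound, ra.upper_bound) != (rb.lower_bound, rb.upper_bound):
            return False
        if {m.id: c for m, c in ra.metabolites.items()} != {
            m.id: c for m, c in rb.metabolites.items()
        }:
            return False
        if ra.gpr.genes != rb.gpr.genes:
            return False
    obj_a = {r.id for r in a.reactions if r.objective_coefficient}
    obj_b = {r.id for r in b.reactions if r.objective_coefficient}
    return obj_a == obj_b
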