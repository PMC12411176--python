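"""On-disk model dialect: JSON models, TSV matrices, solution tables.

JSON is the canonical dialect::

    {"compounds":  [{"id", "mw", "external", "conc_min", "conc_max",
                     "mass_fraction"}],
     "reactions":  [{"id", "stoich": {cid: coef}, "lb", "ub", "internal",
                     "dg0", "kcat", "mass_loss", "kinetics": {...}}],
     "biomass":    {"fractions": {cid: g/g}},
     "units":      [{"id", "mass_fraction", "monomer_stoich", "gating",
                     "k_syn", "k_m"}]}

Unknown keys are ignored with a warning.  TSV import is provided for plain
matrices only.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import KineticLaw
from .model import Compound, ModelValidationError, Network, Reaction
from .solution import FluxSolution

__all__ = [
    "load_model",
    "save_model",
    "load_matrix_tsv",
    "save_solution",
    "load_solution",
    "ModelFormatError",
]

_COMPOUND_KEYS = {"id", "mw", "external", "conc_min", "conc_max", "mass_fraction"}
_REACTION_KEYS = {
    "id", "stoich", "lb", "ub", "internal", "dg0", "kcat", "mass_loss",
    "kinetics",
}
_KINETIC_KEYS = {"kcat", "Ks", "Kp", "orders", "Keq", "kcat_minus", "Km"}
_TOP_KEYS = {"compounds", "reactions", "biomass", "units"}


class ModelFormatError(ValueError):
    """The model file does not parse as the documented dialect."""


def _warn_unknown(keys, known, where: str) -> None:
    extra = set(keys) - known
    if extra:
        warnings.warn(
            f"ignoring unknown fields {sorted(extra)} in {where}", stacklevel=3
        )


def _parse_kinetics(raw: dict, rid: str) -> KineticLaw:
    _warn_unknown(raw, _KINETIC_KEYS, f"kinetics of reaction {rid!r}")
    try:
        return KineticLaw(
            kcat=float(raw["kcat"]),
            Ks={k: float(v) for k, v in raw.get("Ks", {}).items()},
            Kp={k: float(v) for k, v in raw.get("Kp", {}).items()},
            orders={k: int(v) for k, v in raw.get("orders", {}).items()},
            k_eq=None if raw.get("Keq") is None else float(raw["Keq"]),
            kcat_minus=(
                None if raw.get("kcat_minus") is None else float(raw["kcat_minus"])
            ),
            k_m=None if raw.get("Km") is None else float(raw["Km"]),
        )
    except KeyError as exc:
        raise ModelFormatError(
            f"reaction {rid!r}: kinetics missing key {exc.args[0]!r}"
        ) from None


def load_model(path: str | Path) -> Network:
    """Load a network from the JSON dialect.

    Returns a validated Network.  Biomass fractions, when present, are
    attached to the compounds' ``mass_fraction`` and to the network as
    ``net.biomass_fractions``; unit definitions are attached raw as
    ``net.unit_definitions`` for the macro-unit layer to interpret.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: line {exc.lineno}: {exc.msg}") from None
    if not isinstance(raw, dict):
        raise ModelFormatError(f"{path}: top level must be a JSON object")
    _warn_unknown(raw, _TOP_KEYS, str(path))

    compounds = []
    for entry in raw.get("compounds", []):
        if "id" not in entry:
            raise ModelFormatError(f"{path}: compound without 'id'")
        _warn_unknown(entry, _COMPOUND_KEYS, f"compound {entry['id']!r}")
        compounds.append(
            Compound(
                id=str(entry["id"]),
                molecular_weight=(
                    None if entry.get("mw") is None else float(entry["mw"])
                ),
                is_external=bool(entry.get("external", False)),
                conc_min=(
                    None if entry.get("conc_min") is None
                    else float(entry["conc_min"])
                ),
                conc_max=(
                    None if entry.get("conc_max") is None
                    else float(entry["conc_max"])
                ),
                mass_fraction=(
                    None if entry.get("mass_fraction") is None
                    else float(entry["mass_fraction"])
                ),
            )
        )

    reactions = []
    for entry in raw.get("reactions", []):
        if "id" not in entry:
            raise ModelFormatError(f"{path}: reaction without 'id'")
        rid = str(entry["id"])
        _warn_unknown(entry, _REACTION_KEYS, f"reaction {rid!r}")
        if "stoich" not in entry or not isinstance(entry["stoich"], dict):
            raise ModelFormatError(f"{path}: reaction {rid!r}: missing 'stoich'")
        stoich = {str(k): float(v) for k, v in entry["stoich"].items()}
        reactions.append(
            Reaction(
                id=rid,
                stoich=stoich,
                lower_bound=float(entry.get("lb", -1000.0)),
                upper_bound=float(entry.get("ub", 1000.0)),
                is_internal=bool(entry.get("internal", True)),
                dg0_prime=(
                    None if entry.get("dg0") is None else float(entry["dg0"])
                ),
                kcat=None if entry.get("kcat") is None else float(entry["kcat"]),
                kinetic_law=(
                    _parse_kinetics(entry["kinetics"], rid)
                    if entry.get("kinetics")
                    else None
                ),
                allows_mass_loss=bool(entry.get("mass_loss", False)),
            )
        )

    try:
        net = Network(compounds=compounds, reactions=reactions)
    except ModelValidationError:
        raise

    fractions = raw.get("biomass", {}).get("fractions")
    if fractions:
        net.biomass_fractions = {str(k): float(v) for k, v in fractions.items()}
        for c in net.compounds:
            if c.id in net.biomass_fractions:
                c.mass_fraction = net.biomass_fractions[c.id]
    if raw.get("units"):
        net.unit_definitions = raw["units"]
    return net


def save_model(net: Network, path: str | Path) -> None:
    """Write the JSON dialect; load_model(save_model(net)) is the identity
    on the stoichiometric matrix and on all annotated fields."""
    doc: dict = {"compounds": [], "reactions": []}
    for c in net.compounds:
        entry: dict = {"id": c.id}
        if c.molecular_weight is not None:
            entry["mw"] = c.molecular_weight
        if c.is_external:
            entry["external"] = True
        if c.conc_min is not None:
            entry["conc_min"] = c.conc_min
        if c.conc_max is not None:
            entry["conc_max"] = c.conc_max
        if c.mass_fraction is not None:
            entry["mass_fraction"] = c.mass_fraction
        doc["compounds"].append(entry)
    for r in net.reactions:
        entry = {
            "id": r.id,
            "stoich": dict(r.stoich),
            "lb": r.lower_bound,
            "ub": r.upper_bound,
            "internal": r.is_internal,
        }
        if r.dg0_prime is not None:
            entry["dg0"] = r.dg0_prime
        if r.kcat is not None:
            entry["kcat"] = r.kcat
        if r.allows_mass_loss:
            entry["mass_loss"] = True
        law = r.kinetic_law
        if isinstance(law, KineticLaw):
            kin: dict = {"kcat": law.kcat}
            if law.Ks:
                kin["Ks"] = dict(law.Ks)
            if law.Kp:
                kin["Kp"] = dict(law.Kp)
            if law.orders:
                kin["orders"] = dict(law.orders)
            if law.k_eq is not None:
                kin["Keq"] = law.k_eq
            if law.kcat_minus is not None:
                kin["kcat_minus"] = law.kcat_minus
            if law.k_m is not None:
                kin["Km"] = law.k_m
            entry["kinetics"] = kin
        doc["reactions"].append(entry)
    fractions = getattr(net, "biomass_fractions", None)
    if fractions:
        doc["biomass"] = {"fractions": dict(fractions)}
    units = getattr(net, "unit_definitions", None)
    if units:
        doc["units"] = units
    Path(path).write_text(json.dumps(doc, indent=1))


def load_matrix_tsv(path: str | Path) -> np.ndarray:
    """Read a plain numeric TSV matrix (no header, no index)."""
    frame = pd.read_csv(path, sep="\t", header=None)
    return frame.to_numpy(dtype=float)


def save_solution(sol: FluxSolution, path: str | Path) -> None:
    """Write a flux table (TSV) plus a JSON sidecar ``<path>.json``.

    The TSV holds one row per reaction (id, flux, optional dG and enzyme)
    at full precision; infeasible solutions produce an empty table with the
    status recorded in the sidecar.
    """
    path = Path(path)
    columns: dict[str, list] = {"reaction": [], "flux": []}
    if sol.r is not None:
        columns["reaction"] = list(sol.reaction_ids)
        columns["flux"] = [repr(float(v)) for v in sol.r]
        if sol.dg is not None:
            pad = len(sol.r) - len(sol.dg)
            columns["dg"] = [repr(float(v)) for v in sol.dg] + [""] * pad
        if sol.enzymes is not None:
            columns["enzyme"] = [repr(float(v)) for v in sol.enzymes]
    pd.DataFrame(columns).to_csv(path, sep="\t", index=False)
    sidecar = {
        "status": sol.status,
        "objective_value": sol.objective_value,
        "mu": sol.mu,
        "meta": _jsonable(sol.meta),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1)
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def load_solution(path: str | Path) -> FluxSolution:
    """Inverse of save_solution (fluxes bit-exact via repr round trip)."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    frame = pd.read_csv(path, sep="\t", dtype={"reaction": str})
    if frame.empty:
        r = None
        rids: list[str] = []
    else:
        rids = list(frame["reaction"])
        r = np.array([float(v) for v in frame["flux"]])
    dg = None
    if "dg" in frame.columns and not frame.empty:
        vals = [v for v in frame["dg"] if not pd.isna(v) and v != ""]
        dg = np.array([float(v) for v in vals]) if vals else None
    enzymes = None
    if "enzyme" in frame.columns and not frame.empty:
        enzymes = np.array([float(v) for v in frame["enzyme"]])
    return FluxSolution(
        reaction_ids=rids,
        r=r,
        objective_value=sidecar.get("objective_value"),
        status=sidecar["status"],
        mu=sidecar.get("mu"),
        dg=dg,
        enzymes=enzymes,
        meta=sidecar.get("meta", {}),
    )
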