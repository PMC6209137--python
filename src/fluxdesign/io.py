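"""Structured-text configuration files and archive serialization.

All run inputs are plain YAML: tracer species, device measurement
configurations (standard platform templates or explicit isotopomer
selectors), cost parameters and reference fluxes. Pareto archives are
written as CSV with a commented metadata header (seed, search parameters,
context digest) so a run is reproducible from its outputs alone.
"""

from __future__ import annotations

import hashlib
import io as _io
import json

import numpy as np
import pandas as pd
import yaml

from .costs import CostParameters
from .design import DesignContext, DesignVector, ObjectiveVector
from .errors import ConfigurationError
from .labeling import TracerSpecies
from .measurements import ErrorModel, MeasurementGroup, MeasurementSetup, make_device_templates
from .moo import ParetoArchive

__all__ = [
    "load_tracers",
    "save_tracers",
    "load_devices",
    "save_devices",
    "load_costs",
    "save_costs",
    "load_reference",
    "save_reference",
    "write_archive",
    "read_archive",
    "context_digest",
]


def _read_doc(source):
    if isinstance(source, (dict, list)):
        return source
    try:
        import os

        if os.path.exists(str(source)):
            with open(source) as fh:
                return yaml.safe_load(fh)
    except (OSError, ValueError):
        pass
    return yaml.safe_load(source)


# -- tracers ----------------------------------------------------------------


def load_tracers(source) -> list:
    doc = _read_doc(source)
    species = []
    for rec in doc:
        pattern = rec["pattern"]
        if isinstance(pattern, str):
            pattern = tuple(int(c) for c in pattern)
        species.append(
            TracerSpecies(
                name=str(rec["name"]),
                pattern=tuple(pattern),
                purity=float(rec.get("purity", 1.0)),
                price=float(rec.get("price", 0.0)),
            )
        )
    return species


def save_tracers(species, path=None) -> str:
    doc = [
        {
            "name": s.name,
            "pattern": "".join(str(b) for b in s.pattern),
            "purity": s.purity,
            "price": s.price,
        }
        for s in species
    ]
    text = yaml.safe_dump(doc, sort_keys=False)
    if path:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# -- devices ----------------------------------------------------------------

_TEMPLATE_KINDS = ("ms", "msms", "nmr13c", "nmr1h", "irms")


def _group_from_record(rec, network) -> MeasurementGroup:
    pool = str(rec["pool"])
    mets = network.metabolite_index
    if pool not in mets:
        raise ConfigurationError(f"measurement group references unknown pool {pool!r}")
    n = mets[pool].n_carbons
    kind = rec.get("kind", "custom")
    if kind in _TEMPLATE_KINDS:
        tpl = make_device_templates(
            pool,
            n,
            fragment=tuple(rec["fragment"]) if "fragment" in rec else None,
            protonated=tuple(rec["protonated"]) if "protonated" in rec else None,
        )[kind]
        return MeasurementGroup(
            device=str(rec["device"]),
            name=str(rec.get("name", tpl.name)),
            rows=tpl.rows,
            row_labels=tpl.row_labels,
            n_peaks=int(rec.get("n_peaks", 0)),
            normalize=bool(rec.get("normalize", tpl.normalize)),
        )
    rows, labels = [], []
    size = 1 << n
    for ridx, row in enumerate(rec["rows"]):
        coefs = np.zeros(size)
        if "isotopomers" in row:
            for bits in row["isotopomers"]:
                if len(bits) != n or any(c not in "01" for c in bits):
                    raise ConfigurationError(
                        f"bad isotopomer selector {bits!r} for pool {pool!r}"
                    )
                mask = sum(1 << i for i, c in enumerate(bits) if c == "1")
                coefs[mask] = 1.0
        elif "mass" in row:
            m = int(row["mass"])
            for mask in range(size):
                if bin(mask).count("1") == m:
                    coefs[mask] = 1.0
        elif "position" in row:
            p = int(row["position"])
            for mask in range(size):
                if (mask >> p) & 1:
                    coefs[mask] = 1.0
        else:
            raise ConfigurationError(
                "custom row needs an 'isotopomers', 'mass' or 'position' selector"
            )
        rows.append({pool: coefs})
        labels.append(str(row.get("label", f"{pool}[{ridx}]")))
    return MeasurementGroup(
        device=str(rec["device"]),
        name=str(rec["name"]),
        rows=rows,
        row_labels=labels,
        n_peaks=int(rec.get("n_peaks", 0)),
        normalize=bool(rec.get("normalize", False)),
    )


def load_devices(source, network) -> MeasurementSetup:
    """Device file -> measurement setup template (replicates all 1)."""
    doc = _read_doc(source)
    groups, models = [], {}
    for dev in doc["devices"]:
        name = str(dev["name"])
        em = dev["error_model"]
        models[name] = ErrorModel(
            device=name,
            b1=float(em["b1"]),
            b2=float(em["b2"]),
            scaling=em.get("scaling", "jackknife"),
        )
        for rec in dev["groups"]:
            rec = dict(rec)
            rec["device"] = name
            groups.append(_group_from_record(rec, network))
    return MeasurementSetup(
        groups=groups,
        n_rep=[1] * len(groups),
        error_models=models,
        n_max=int(doc.get("n_max", 10)),
    )


def save_devices(setup: MeasurementSetup, path=None) -> str:
    """Serialize groups by explicit isotopomer selectors (round-trip safe)."""
    devices = {}
    for g in setup.groups:
        dev = devices.setdefault(
            g.device,
            {
                "name": g.device,
                "error_model": {
                    "b1": setup.error_models[g.device].b1,
                    "b2": setup.error_models[g.device].b2,
                    "scaling": setup.error_models[g.device].scaling,
                },
                "groups": [],
            },
        )
        pool = g.pools[0]
        rows = []
        for coefs, label in zip(g.rows, g.row_labels):
            vec = coefs[pool]
            n = int(np.log2(vec.size))
            bits = [
                "".join("1" if (m >> i) & 1 else "0" for i in range(n))
                for m in range(vec.size)
                if vec[m] > 0
            ]
            rows.append({"isotopomers": bits, "label": label})
        dev["groups"].append(
            {
                "pool": pool,
                "name": g.name,
                "n_peaks": g.n_peaks,
                "normalize": g.normalize,
                "rows": rows,
            }
        )
    doc = {"n_max": setup.n_max, "devices": list(devices.values())}
    text = yaml.safe_dump(doc, sort_keys=False)
    if path:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# -- costs and reference fluxes --------------------------------------------


def load_costs(source) -> CostParameters:
    doc = _read_doc(source)
    return CostParameters(
        tracer_prices={str(k): float(v) for k, v in doc.get("tracer_prices", {}).items()},
        substrate_mass=float(doc.get("substrate_mass", 5.0)),
        c_exp=float(doc.get("c_exp", 0.0)),
        c_work=float(doc.get("c_work", 30.0)),
        t_work_exp=float(doc.get("t_work_exp", 0.0)),
        c_sample=float(doc.get("c_sample", 50.0)),
        n_samples=int(doc.get("n_samples", 10)),
        t_work_ana=float(doc.get("t_work_ana", 0.05)),
    )


def save_costs(params: CostParameters, path=None) -> str:
    doc = {
        "tracer_prices": dict(params.tracer_prices),
        "substrate_mass": params.substrate_mass,
        "c_exp": params.c_exp,
        "c_work": params.c_work,
        "t_work_exp": params.t_work_exp,
        "c_sample": params.c_sample,
        "n_samples": params.n_samples,
        "t_work_ana": params.t_work_ana,
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def load_reference(source, param) -> np.ndarray:
    """Reference free fluxes from {free: {name: value}} keyed by free names."""
    doc = _read_doc(source)
    free = doc["free"]
    missing = [nm for nm in param.free_flux_names if nm not in free]
    if missing:
        raise ConfigurationError(f"reference fluxes missing entries: {missing}")
    return np.array([float(free[nm]) for nm in param.free_flux_names])


def save_reference(param, reference, path=None) -> str:
    doc = {
        "free": {
            nm: float(v) for nm, v in zip(param.free_flux_names, reference)
        }
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# -- archives ---------------------------------------------------------------


def context_digest(context: DesignContext) -> str:
    """Stable digest of the design context for run metadata."""
    payload = {
        "network": context.param.network.name,
        "free": context.param.free_flux_names,
        "reference": [float(v) for v in context.reference_free],
        "species": [s.name for s in context.species],
        "groups": [g.name for g in context.setup_template.groups],
        "objectives": context.objectives,
        "n_cle": context.n_cle,
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_archive(archive: ParetoArchive, context: DesignContext, path, metadata=None) -> None:
    from .analysis import front_table

    df = front_table(archive, context)
    meta = dict(metadata or {})
    meta.setdefault("format", "fluxdesign-archive/1")
    meta["context_digest"] = context_digest(context)
    with open(path, "w") as fh:
        for key in sorted(meta):
            fh.write(f"# {key}: {meta[key]}\n")
        # 17 significant digits: float64 survives the text round trip exactly
        df.to_csv(fh, index=False, float_format="%.17g")


def read_archive(path, context: DesignContext):
    """Rebuild (archive, metadata) from an archive file.

    Objective vectors and designs round-trip exactly; criteria and cost
    columns are restored from the table.
    """
    meta = {}
    body = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            else:
                body.append(line)
    df = pd.read_csv(_io.StringIO("".join(body)), float_precision="round_trip")
    names = context.objective_names
    archive = ParetoArchive(capacity=max(len(df), 1))
    from .costs import CostBreakdown
    from .criteria import CriteriaValues

    for _, row in df.iterrows():
        obj = np.array([row[nm] for nm in names])
        design = DesignVector.from_json(row["design"], context)
        crit = CriteriaValues(
            dof=int(row["p"]),
            phi_d=row["phi_d"],
            phi_a=row["phi_a"],
            phi_e=row["phi_e"],
        )
        cost = CostBreakdown(
            experimental=float(row["cost_experimental"]),
            analytical=float(row["cost_analytical"]),
        )
        frozen = [] if pd.isna(row["frozen"]) or row["frozen"] == "" else str(row["frozen"]).split(";")
        result = ObjectiveVector(
            names=names,
            values=obj,
            p=int(row["p"]),
            criteria=crit,
            cost=cost,
            frozen=frozen,
            design=design,
        )
        archive.entries.append((obj, result))
    return archive, meta
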