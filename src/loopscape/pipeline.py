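"""End-to-end loop analysis: superposition, flexibility, contacts, loop
metrics and conformer labels from a single config.

The config is a plain dict (or a YAML file with the same shape):

.. code-block:: yaml

    structures:
      - {path: a.pdb, chains: [A]}        # or in-memory Structure objects
    loops:
      - {name: L1, start: 39, end: 54}
    reference: {structure: a, chain: A}   # conformer-label reference
    classify: {start: 301, end: 311, threshold: 3.0, alternate_label: alternate}
    modes: [core-frame, loop-local]
    cutoffs: {hbond_dmax: 3.5, phobic_dmax: 4.5, flex_threshold: 0.5}

Reports are plain serializable dicts; every number is traceable to the
operation and parameter set recorded alongside it.  Partial failures
(one unreadable chain) are reported per item, not fatal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .contacts import contact_counts, loop_contact_report
from .errors import ConfigurationError, LoopscapeError
from .flexibility import normalize_bfactors, region_flexibility
from .loop_analysis import (TSABGL_LOOPS, classify_conformer, loop_charge,
                            pocket_geometry, per_loop_rmsd)
from .structure_io import RegionSpec, Structure, parse_structure
from .superpose import displacement_profile

logger = logging.getLogger("loopscape")

__all__ = ["AnalysisReport", "run_analysis", "load_config"]

REPORT_SCHEMA_VERSION = 1

DEFAULT_CUTOFFS = {
    "hbond_dmax": 3.5,
    "phobic_dmax": 4.5,
    "seq_sep_min": 2,
    "flex_threshold": 0.5,
    "classify_threshold": 3.0,
}


@dataclass
class AnalysisReport:
    """Full analysis output; serializable to JSON."""

    config: dict
    chains: list[str] = field(default_factory=list)
    per_loop_rmsd: dict = field(default_factory=dict)
    flexibility: dict = field(default_factory=dict)
    conformers: dict = field(default_factory=dict)
    contacts: dict = field(default_factory=dict)
    pocket: dict = field(default_factory=dict)
    charges: dict = field(default_factory=dict)
    errors: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return _jsonable({
            "schema_version": REPORT_SCHEMA_VERSION,
            "config": self.config,
            "chains": self.chains,
            "per_loop_rmsd": self.per_loop_rmsd,
            "flexibility": self.flexibility,
            "conformers": self.conformers,
            "contacts": self.contacts,
            "pocket": self.pocket,
            "charges": self.charges,
            "errors": self.errors,
            "provenance": self.provenance,
        })

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return _jsonable(x.tolist())
    if isinstance(x, (np.floating, float)):
        return round(float(x), 6)
    if isinstance(x, np.integer):
        return int(x)
    return x


def load_config(path: str | Path) -> dict:
    import yaml
    with open(path) as fh:
        return yaml.safe_load(fh)


def _parse_regions(items) -> list[RegionSpec]:
    out = []
    for it in items:
        if isinstance(it, RegionSpec):
            out.append(it)
        else:
            out.append(RegionSpec(it["name"], int(it["start"]), int(it["end"]),
                                  it.get("chain", "*")))
    return out


def run_analysis(config: dict) -> AnalysisReport:
    """Run the whole pipeline from a config dict (see module docstring).

    ``config["structures"]`` entries may carry ``path`` (file to parse) or
    ``structure`` (an in-memory :class:`Structure`).  Deterministic for
    fixed inputs and config.
    """
    loops = _parse_regions(config.get("loops", TSABGL_LOOPS))
    cutoffs = {**DEFAULT_CUTOFFS, **config.get("cutoffs", {})}
    modes = list(config.get("modes", ["core-frame", "loop-local"]))
    report = AnalysisReport(config={k: v for k, v in config.items()
                                    if k != "structures"})
    report.config["loops"] = [vars(r) for r in loops]
    report.config["cutoffs"] = cutoffs
    report.provenance = {"package": "loopscape", "version": __version__,
                         "modes": modes}

    # ---- load structures -------------------------------------------------
    ensemble: list[tuple[Structure, str]] = []
    for entry in config.get("structures", []):
        try:
            if "structure" in entry:
                s = entry["structure"]
            else:
                s = parse_structure(entry["path"], entry.get("format"))
            chains = entry.get("chains") or s.protein_chain_ids()
            for cid in chains:
                s.chain(cid)  # raises if absent
                ensemble.append((s, cid))
        except LoopscapeError as exc:
            report.errors.append({"input": str(entry.get("path", "?")),
                                  "error": str(exc)})
            logger.warning("skipping input %s: %s", entry, exc)
    if not ensemble:
        raise ConfigurationError(
            "no valid chains to analyse; per-input errors: "
            + json.dumps(report.errors))
    report.chains = [f"{s.id}:{cid}" for s, cid in ensemble]

    # ---- per-loop r.m.s.d. (needs >= 2 chains) ---------------------------
    if len(ensemble) >= 2:
        for mode in modes:
            try:
                res = per_loop_rmsd(ensemble, loops, mode=mode)
                report.per_loop_rmsd[mode] = {
                    "labels": res.labels,
                    "matrices": {k: v for k, v in res.matrices.items()},
                    "summary": {k: {"min": v[0], "max": v[1]}
                                for k, v in res.summary().items()},
                }
            except LoopscapeError as exc:
                report.errors.append({"stage": f"per_loop_rmsd[{mode}]",
                                      "error": str(exc)})

    # ---- flexibility, contacts, charges per chain ------------------------
    for s, cid in ensemble:
        label = f"{s.id}:{cid}"
        try:
            prof = normalize_bfactors(s, scope="chain", chain_id=cid)
            report.flexibility[label] = {
                rg.name: vars(region_flexibility(
                    prof, rg, threshold=cutoffs["flex_threshold"]))
                for rg in loops}
        except LoopscapeError as exc:
            report.errors.append({"stage": f"flexibility[{label}]",
                                  "error": str(exc)})
        try:
            rep = loop_contact_report(
                s, cid, loops, hbond_dmax=cutoffs["hbond_dmax"],
                phobic_dmax=cutoffs["phobic_dmax"],
                seq_sep_min=cutoffs["seq_sep_min"])
            report.contacts[label] = contact_counts(rep)
        except LoopscapeError as exc:
            report.errors.append({"stage": f"contacts[{label}]",
                                  "error": str(exc)})
        try:
            report.charges[label] = {rg.name: loop_charge(s, rg, cid)
                                     for rg in loops}
        except LoopscapeError as exc:
            report.errors.append({"stage": f"charges[{label}]",
                                  "error": str(exc)})

    # ---- conformer labels against the declared reference -----------------
    ref_cfg = config.get("reference")
    if ref_cfg and len(ensemble) >= 2:
        ref = next(((s, cid) for s, cid in ensemble
                    if (s.id == ref_cfg.get("structure")
                        or ref_cfg.get("structure") is None)
                    and cid == ref_cfg.get("chain", cid)), ensemble[0])
        cls_cfg = config.get("classify", {})
        cls_region = RegionSpec("classify",
                                int(cls_cfg.get("start", loops[-2].start)),
                                int(cls_cfg.get("end", loops[-2].end)))
        threshold = float(cls_cfg.get("threshold",
                                      cutoffs["classify_threshold"]))
        alt = cls_cfg.get("alternate_label", "alternate")
        ref_label = f"{ref[0].id}:{ref[1]}"
        report.conformers["reference"] = ref_label
        report.conformers["labels"] = {}
        for s, cid in ensemble:
            label = f"{s.id}:{cid}"
            if (s, cid) == ref:
                continue
            try:
                prof = displacement_profile(ref[0], ref[1], s, cid,
                                            core=loops, core_is_exclusion=True)
                c = classify_conformer(prof, cls_region, threshold, alt)
                report.conformers["labels"][label] = {
                    "label": c.label, "max_disp": c.max_disp,
                    "argmax_residue": c.argmax_residue,
                    "region": [c.region.start, c.region.end],
                    "threshold": c.threshold,
                }
            except LoopscapeError as exc:
                report.errors.append({"stage": f"conformer[{label}]",
                                      "error": str(exc)})

    # ---- pocket geometry (needs an L2/L3 pair) ---------------------------
    by_name = {rg.name: rg for rg in loops}
    if "L2" in by_name and "L3" in by_name:
        for s, cid in ensemble:
            label = f"{s.id}:{cid}"
            try:
                geo = pocket_geometry(s, cid, by_name["L2"], by_name["L3"])
                report.pocket[label] = vars(geo)
            except LoopscapeError as exc:
                report.errors.append({"stage": f"pocket[{label}]",
                                      "error": str(exc)})
    return report
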