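"""File formats and configuration.

Conventions fixed across all files: time in minutes, concentrations in mM,
comma-separated UTF-8 CSV with '.' decimal and a mandatory header.  Trace
files use the columns ``time_min, gj_norm, fi_norm, mg1_mM, mg2_mM,
variant, protocol_id`` (optional columns may be absent).  Datasets are a
directory of trace CSVs plus a JSON manifest recording the generator
configuration and per-trace seeds, so a dataset can be regenerated
byte-identically from its manifest.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .pair import Protocol, TraceSet, VjPulse
from .schemes import RateParams

__all__ = [
    "read_dataset",
    "protocol_to_dict",
    "protocol_from_dict",
    "rate_params_to_dict",
    "rate_params_from_dict",
    "write_manifest",
    "read_manifest",
    "write_fit_report",
    "SimulateConfig",
    "MakeDataConfig",
    "FitConfig",
    "SelectConfig",
    "RecoverConfig",
    "load_config",
    "dump_resolved_config",
]


# -- plain-dict serialisation of the science types -----------------------

def protocol_to_dict(protocol: Protocol) -> dict:
    d = {
        "duration": protocol.duration,
        "pipette_mg": list(protocol.pipette_mg),
        "clamp": list(protocol.clamp),
        "initial_mg": list(protocol.initial_mg) if protocol.initial_mg else None,
        "initial_state_mg": list(protocol.initial_state_mg),
        "sample_interval": protocol.sample_interval,
        "trap_factor": protocol.trap_factor,
        "protocol_id": protocol.protocol_id,
    }
    wf = protocol.vj_waveform
    if wf is None:
        d["vj_pulse"] = None
    elif isinstance(wf, VjPulse):
        d["vj_pulse"] = dataclasses.asdict(wf)
    else:
        raise ValueError("only VjPulse waveforms are serialisable")
    return d


def protocol_from_dict(d: dict) -> Protocol:
    pulse = d.get("vj_pulse")
    return Protocol(
        duration=d["duration"],
        pipette_mg=tuple(d["pipette_mg"]),
        clamp=tuple(bool(c) for c in d["clamp"]),
        initial_mg=tuple(d["initial_mg"]) if d.get("initial_mg") else None,
        initial_state_mg=tuple(d.get("initial_state_mg", (0.0, 0.0))),
        sample_interval=d.get("sample_interval", 0.05),
        vj_waveform=VjPulse(**pulse) if pulse else None,
        trap_factor=d.get("trap_factor"),
        protocol_id=d.get("protocol_id", "custom"),
    )


def rate_params_to_dict(params: RateParams) -> dict:
    return params.as_dict()


def rate_params_from_dict(d: dict) -> RateParams:
    return RateParams(**d)


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def write_fit_report(result, out_dir, stem: str = "fit") -> tuple[Path, Path]:
    """Write a fit as a human-readable report plus a machine-readable table.

    Returns the (report, table) paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {"scheme": result.scheme_label, "parameter": name, "estimate": value}
        for name, value in result.params.as_dict().items()
    ]
    table = pd.DataFrame(rows)
    table["sse"] = result.sse
    table["n"] = result.n_points
    table["k"] = result.k_params
    table["seed"] = result.seed
    table_path = out_dir / f"{stem}_params.csv"
    table.to_csv(table_path, index=False)

    lines = [
        f"scheme: {result.scheme_label}",
        f"sse: {result.sse:.8g}",
        f"n_points: {result.n_points}",
        f"k_params: {result.k_params}",
        f"seed: {result.seed}",
        f"n_restarts: {result.n_restarts}",
        f"failed_restarts: {result.n_failed_restarts}",
        "parameters:",
    ]
    for name, value in result.params.as_dict().items():
        lines.append(f"  {name}: {value:.6g}")
    lines.append("restart_sse: " + ", ".join(f"{v:.6g}" for v in result.restart_sse))
    report_path = out_dir / f"{stem}_report.txt"
    report_path.write_text("\n".join(lines) + "\n")
    return report_path, table_path


def read_dataset(data_dir, variants: list[str] | None = None) -> dict:
    """Load a dataset directory (trace CSVs + manifest) into per-variant
    :class:`~cx36mg.fitting.FitDataset` objects."""
    from .fitting import FitDataset, FitEntry  # deferred: io stays import-light

    data_dir = Path(data_dir)
    manifest = read_manifest(data_dir / "manifest.json")
    protocols = {
        d["protocol_id"]: protocol_from_dict(d) for d in manifest["protocols"]
    }
    entries: dict[str, list] = {}
    for record in manifest["traces"]:
        variant = record["variant"]
        if variants is not None and variant not in variants:
            continue
        if "file" not in record:
            raise FileNotFoundError(
                f"manifest trace record has no file: {record}"
            )
        trace = TraceSet.read_csv(data_dir / record["file"])
        protocol = protocols[record["protocol_id"]]
        channels = ("gj", "fi") if not protocol.clamp[0] else ("gj",)
        entries.setdefault(variant, []).append(
            FitEntry(trace=trace, protocol=protocol, channels=channels)
        )
    return {
        variant: FitDataset(entries=items, variant=variant)
        for variant, items in entries.items()
    }


# -- command configuration (YAML/JSON) ------------------------------------

class SimulateConfig(BaseModel):
    variant: str = "WT"
    scheme: str = "Model 5, Hill"
    protocol: str = "sym_5"  # "sym_<mM>", "asym_<mM>" or "vjramp_<mM>"
    duration: float = 5.0
    sample_interval: float = 0.05
    trap: float | None = Field(default=None, ge=0.0, le=1.0)
    solver: str = "LSODA"
    out_dir: str = "results/simulate"


class MakeDataConfig(BaseModel):
    variants: list[str] = ["WT", "E3Q", "E8Q", "A13K", "H18K"]
    protocols: list[str] = ["asym_5", "asym_10", "sym_5", "sym_0.01"]
    duration: float = 5.0
    sample_interval: float = 0.05
    sigma_gj: float = 0.02
    sigma_fi: float = 0.02
    n_replicates: int = 5
    seed: int = 0
    out_dir: str = "results/dataset"


class FitConfig(BaseModel):
    data_dir: str
    variant: str = "WT"
    scheme: str = "Model 5, Hill"
    n_restarts: int = 20
    seed: int = 0
    p_leak: float = 0.0
    out_dir: str = "results/fit"


class SelectConfig(BaseModel):
    data_dir: str
    variant: str = "WT"
    schemes: list[str] | None = None
    n_restarts: int = 10
    seed: int = 0
    validation_protocols: list[str] = []
    out_dir: str = "results/select"


class RecoverConfig(BaseModel):
    variant: str = "WT"
    scheme: str = "Model 5, Hill"
    protocols: list[str] = ["asym_10", "sym_5"]
    sigma: float = 0.02
    n_replicates: int = 5
    n_seeds: int = 5
    n_restarts: int = 8
    seed: int = 0
    out_dir: str = "results/recover"


def load_config(path, model: type[BaseModel], overrides: dict | None = None):
    """Load a YAML/JSON config file into a validated config model."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    return model.model_validate(data)


def dump_resolved_config(config: BaseModel, out_dir) -> Path:
    """Write the fully resolved config next to a command's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "resolved_config.yaml"
    path.write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))
    return path
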