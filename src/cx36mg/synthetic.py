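"""Synthetic trace datasets emulating the dual whole-cell recordings.

The generator simulates the cell-pair model under the study's protocols
(asymmetric pipette Mg2+ at 5 or 10 mM with simultaneous conductance and
fluorescence readout, symmetric 5 mM decay, low-Mg 0.01 mM control, and a
Vj-pulse closure/recovery protocol) and adds i.i.d. Gaussian measurement
noise to the normalised series.  Noise is purely observational: the
concentrations and state probabilities inside the generator stay exact.
Negative noisy samples are clipped at zero (the measurements are
non-negative by construction) and the clip count recorded per trace.

Every trace gets its own child seed spawned deterministically from the
master seed, so a dataset is byte-identical given the same configuration
and can be regenerated from its manifest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .fitting import FitDataset, FitEntry, GatingModelFitter
from .pair import (
    Protocol,
    TraceSet,
    VjModulation,
    asymmetric_protocol,
    simulate_pair,
    symmetric_protocol,
    vj_pulse_protocol,
    vj_ramp_experiment,
)
from .schemes import VARIANT_PARAMS, KineticScheme, RateParams, get_scheme

__all__ = [
    "GeneratorConfig",
    "protocol_from_spec",
    "add_noise",
    "generate_dataset",
    "config_from_manifest",
    "generate_recovery_suite",
    "recovery_study",
]

DEFAULT_PROTOCOL_SPECS = ("asym_5", "asym_10", "sym_5", "sym_0.01")


def protocol_from_spec(
    spec: str, duration: float = 5.0, sample_interval: float = 0.05
) -> Protocol:
    """Build a protocol from a short spec string.

    ``asym_<mM>``: donor pipette at <mM>, recipient unclamped near zero;
    ``sym_<mM>``: both pipettes at <mM>; ``vjramp_<mM>``: symmetric <mM>
    with a brief Vj pulse and a recovery phase.
    """
    kind, _, value = spec.partition("_")
    mg = float(value)
    if kind == "asym":
        return asymmetric_protocol(mg, duration=duration, sample_interval=sample_interval)
    if kind == "sym":
        return symmetric_protocol(mg, duration=duration, sample_interval=sample_interval)
    if kind == "vjramp":
        return vj_pulse_protocol(
            mg, duration=max(duration, 11.0), sample_interval=sample_interval
        )
    raise ValueError(f"unknown protocol spec {spec!r}")


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Defaults reproduce the published recording conditions: the five Cx36
    variants with their estimated parameter sets, 5-minute protocols sampled
    every 0.05 min (the cadence of the repeated low-amplitude voltage
    ramps used to track conductance), additive Gaussian noise with sigma
    0.02 on both normalised channels, and five replicates per condition.
    """

    variants: dict[str, RateParams] = field(
        default_factory=lambda: dict(VARIANT_PARAMS)
    )
    protocols: list[Protocol] = field(
        default_factory=lambda: [protocol_from_spec(s) for s in DEFAULT_PROTOCOL_SPECS]
    )
    scheme: str = "Model 5, Hill"
    sigma_gj: float = 0.02
    sigma_fi: float = 0.02
    n_replicates: int = 5
    seed: int = 0
    vj_modulation: VjModulation = field(default_factory=VjModulation)

    def __post_init__(self) -> None:
        if self.sigma_gj < 0 or self.sigma_fi < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def add_noise(
    trace: TraceSet,
    sigma_gj: float,
    sigma_fi: float,
    rng: np.random.Generator,
) -> tuple[TraceSet, int]:
    """Additive Gaussian measurement noise on the normalised series.

    Returns the noisy trace and the number of samples clipped at zero.
    """
    gj = trace.gj_norm + rng.normal(0.0, sigma_gj, size=len(trace))
    clips = int(np.sum(gj < 0))
    gj = np.clip(gj, 0.0, None)
    fi = None
    if trace.fi_norm is not None:
        fi = trace.fi_norm + rng.normal(0.0, sigma_fi, size=len(trace))
        clips += int(np.sum(fi < 0))
        fi = np.clip(fi, 0.0, None)
    noisy = TraceSet(
        time=trace.time.copy(),
        gj_norm=gj,
        fi_norm=fi,
        mg1=None if trace.mg1 is None else trace.mg1.copy(),
        mg2=None if trace.mg2 is None else trace.mg2.copy(),
        variant=trace.variant,
        protocol_id=trace.protocol_id,
    )
    return noisy, clips


def _entry_channels(protocol: Protocol) -> tuple[str, ...]:
    # the fluorescence proxy is informative only when cell 1 is unclamped
    return ("gj", "fi") if not protocol.clamp[0] else ("gj",)


def _simulate_protocol(
    scheme: KineticScheme,
    params: RateParams,
    protocol: Protocol,
    mod: VjModulation,
    variant: str,
) -> TraceSet:
    if protocol.vj_waveform is not None:
        return vj_ramp_experiment(scheme, params, protocol, mod, variant=variant)
    return simulate_pair(scheme, params, protocol, variant=variant)


def generate_dataset(
    config: GeneratorConfig, out_dir: str | Path | None = None
) -> tuple[dict[str, FitDataset], dict]:
    """Simulate every variant x protocol x replicate and add noise.

    Returns per-variant datasets and a manifest.  With ``out_dir`` set,
    trace CSVs and ``manifest.json`` are written there.
    """
    scheme = get_scheme(config.scheme)
    root = np.random.SeedSequence(config.seed)
    datasets: dict[str, FitDataset] = {}
    trace_records = []
    spawn_index = 0
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    # canonical order: independent of dict insertion order so that a
    # manifest round-trip reproduces the same seed assignment
    for variant in sorted(config.variants):
        params = config.variants[variant]
        entries = []
        for protocol in config.protocols:
            base = _simulate_protocol(
                scheme, params, protocol, config.vj_modulation, variant
            )
            for replicate in range(config.n_replicates):
                child = root.spawn(1)[0]
                rng = np.random.default_rng(child)
                noisy, clips = add_noise(base, config.sigma_gj, config.sigma_fi, rng)
                entries.append(
                    FitEntry(
                        trace=noisy,
                        protocol=protocol,
                        channels=_entry_channels(protocol),
                    )
                )
                record = {
                    "variant": variant,
                    "protocol_id": protocol.protocol_id,
                    "replicate": replicate,
                    "spawn_index": spawn_index,
                    "clip_count": clips,
                }
                if out_path is not None:
                    fname = f"{variant}_{protocol.protocol_id}_rep{replicate}.csv"
                    noisy.write_csv(out_path / fname)
                    record["file"] = fname
                trace_records.append(record)
                spawn_index += 1
        datasets[variant] = FitDataset(entries=entries, variant=variant)

    manifest = {
        "master_seed": config.seed,
        "scheme": config.scheme,
        "sigma_gj": config.sigma_gj,
        "sigma_fi": config.sigma_fi,
        "n_replicates": config.n_replicates,
        "variants": {
            name: _io.rate_params_to_dict(p) for name, p in config.variants.items()
        },
        "protocols": [_io.protocol_to_dict(p) for p in config.protocols],
        "vj_modulation": dataclasses.asdict(config.vj_modulation),
        "traces": trace_records,
    }
    if out_path is not None:
        _io.write_manifest(manifest, out_path / "manifest.json")
    return datasets, manifest


def config_from_manifest(manifest: dict) -> GeneratorConfig:
    """Reconstruct the generator configuration recorded in a manifest."""
    return GeneratorConfig(
        variants={
            name: _io.rate_params_from_dict(d)
            for name, d in manifest["variants"].items()
        },
        protocols=[_io.protocol_from_dict(d) for d in manifest["protocols"]],
        scheme=manifest["scheme"],
        sigma_gj=manifest["sigma_gj"],
        sigma_fi=manifest["sigma_fi"],
        n_replicates=manifest["n_replicates"],
        seed=manifest["master_seed"],
        vj_modulation=VjModulation(**manifest["vj_modulation"]),
    )


def generate_recovery_suite(
    truth: RateParams,
    scheme: str | KineticScheme = "Model 5, Hill",
    sigma: float = 0.02,
    n_replicates: int = 5,
    seed: int = 0,
    protocol_specs: tuple[str, ...] = ("asym_10", "sym_5"),
    variant: str = "truth",
) -> tuple[FitDataset, dict]:
    """Dataset generated from known parameters plus a ground-truth manifest,
    for automated bias/RMSE evaluation of the fitting pipeline."""
    scheme_label = scheme if isinstance(scheme, str) else scheme.label
    config = GeneratorConfig(
        variants={variant: truth},
        protocols=[protocol_from_spec(s) for s in protocol_specs],
        scheme=scheme_label,
        sigma_gj=sigma,
        sigma_fi=sigma,
        n_replicates=n_replicates,
        seed=seed,
    )
    datasets, manifest = generate_dataset(config)
    truth_manifest = {
        "truth": _io.rate_params_to_dict(truth),
        "scheme": scheme_label,
        "sigma": sigma,
        "seed": seed,
        "protocols": list(protocol_specs),
        "generator_manifest": manifest,
    }
    return datasets[variant], truth_manifest


def _recovery_bounds(truth: RateParams, scheme: KineticScheme) -> dict:
    """Box bounds spanning the generating values by a factor of ten each way."""
    bounds = {}
    for name in ("k1", "k2", "k3", "k4", "p"):
        value = getattr(truth, name)
        if value <= 0:
            bounds[name] = (1e-8, 1e-2)
        else:
            bounds[name] = (value / 10.0, value * 10.0)
    if scheme.is_hill:
        bounds["n"] = (0.01, 5.0)
    return bounds


def recovery_study(
    truth: RateParams,
    scheme: str | KineticScheme = "Model 5, Hill",
    sigma: float = 0.02,
    n_replicates: int = 5,
    n_seeds: int = 5,
    n_restarts: int = 8,
    seed: int = 0,
    protocol_specs: tuple[str, ...] = ("asym_10", "sym_5"),
    bounds: dict | None = None,
    max_nfev: int = 120,
) -> pd.DataFrame:
    """Repeated generate-and-fit rounds against known parameters.

    Returns one row per fitting seed with the estimates, plus aggregate
    rows for the seed-mean, bias and RMSE of each parameter.  Search bounds
    default to the generating values scaled by a factor of ten each way.
    """
    scheme_obj = get_scheme(scheme) if isinstance(scheme, str) else scheme
    if bounds is None:
        bounds = _recovery_bounds(truth, scheme_obj)
    names = ["k1", "k2", "k3", "k4", "p"] + (["n"] if scheme_obj.is_hill else [])
    rows = []
    for i in range(n_seeds):
        run_seed = seed + i
        dataset, _ = generate_recovery_suite(
            truth,
            scheme_obj,
            sigma=sigma,
            n_replicates=n_replicates,
            seed=run_seed,
            protocol_specs=protocol_specs,
        )
        fitter = GatingModelFitter(
            scheme=scheme_obj,
            bounds=bounds,
            n_restarts=n_restarts,
            random_state=run_seed,
            max_nfev=max_nfev,
        )
        fitter.fit(dataset)
        row = {"seed": run_seed, "sse": fitter.sse_}
        row.update({name: getattr(fitter.params_, name) for name in names})
        rows.append(row)
    table = pd.DataFrame(rows)
    summary = {"seed": "summary", "sse": table["sse"].mean()}
    for name in names:
        true_value = getattr(truth, name)
        estimates = table[name].to_numpy()
        summary[name] = estimates.mean()
        summary[f"{name}_bias"] = estimates.mean() - true_value
        summary[f"{name}_rmse"] = float(np.sqrt(np.mean((estimates - true_value) ** 2)))
    return pd.concat([table, pd.DataFrame([summary])], ignore_index=True)
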