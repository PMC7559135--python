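"""End-to-end run: inputs -> tissue fields -> flow -> transport -> Vd report.

Deterministic given the config seed; every stage logs its parameters and
array checksums so a rerun can be verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import dce, flow, io, phantom, quantify, tissue, transport

__all__ = ["run_pipeline"]


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _tissue_config(cfg: dict) -> tissue.TissueConfig:
    t = cfg["tissue"]

    def poro(block):
        return tissue.PoroelasticParams(
            alpha=block["alpha"], B_drained=block["B_drained"], G_shear=block["G_shear"]
        )

    return tissue.TissueConfig(
        adc_normal=t["adc_normal"],
        adc_csf=t["adc_csf"],
        phi_normal=t["phi_normal"],
        phi_min=t["phi_min"],
        K_ref=t["K_ref"],
        beta2_ref=t["beta2_ref"],
        gray=poro(t["gray"]),
        white=poro(t["white"]),
        tumor=poro(t["tumor"]),
    )


def run_pipeline(cfg: dict, outdir) -> dict:
    """Run the full simulation described by ``cfg``; write artifacts to ``outdir``.

    Returns a summary dict (also written as ``run_log.json``) with stage
    parameters, checksums and the final distribution-volume report.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"stages": {}, "seed": cfg.get("seed", 0)}

    # --- inputs ------------------------------------------------------------
    if cfg["phantom"]["use"]:
        spec = (
            phantom.PhantomSpec.compact(seed=cfg.get("seed", 0))
            if cfg["phantom"].get("compact", True)
            else phantom.PhantomSpec(seed=cfg.get("seed", 0))
        )
        ph = phantom.make_phantom(spec)
        tmap, adc_field, ktrans_field = ph.tissue, ph.adc, ph.ktrans
        tumor_mask, coverage = ph.tumor_mask, ph.dce_coverage
        log["stages"]["phantom"] = {
            "spec": {"shape": list(spec.shape), "seed": spec.seed},
            "truth": ph.truth,
        }
    else:
        inputs = cfg["inputs"]
        tmap_field = io.read_volume(inputs["tissue_map"])
        adc_field = io.read_volume(inputs["adc"], units="cm^2/s",
                                   expected_grid=tmap_field.grid)
        wf = None
        if inputs.get("white_fraction"):
            wf = io.read_volume(inputs["white_fraction"],
                                expected_grid=tmap_field.grid).values
        tmap = tissue.TissueClassMap(
            tmap_field.grid, tmap_field.values.astype(int), white_fraction=wf
        )
        if inputs.get("ktrans"):
            ktrans_field = io.read_volume(inputs["ktrans"], units="1/s",
                                          expected_grid=tmap_field.grid)
            coverage = ktrans_field.values > 0
        else:
            ktrans_field = None
            coverage = np.zeros(tmap.grid.shape, dtype=bool)
        tumor_mask = tmap.mask(tissue.TissueClass.TUMOR_ENHANCING)

    grid = tmap.grid

    # --- tissue fields -------------------------------------------------------
    tcfg = _tissue_config(cfg)
    hyd = tissue.build_hydraulic_state(tmap, adc_field, tcfg)
    alpha, B = tissue.build_poroelastic_fields(tmap, tcfg)
    io.write_volume(tissue.ScalarField(grid, hyd.phi0, "1"), outdir / "phi0.nii.gz")
    log["stages"]["tissue"] = {
        "phi0_checksum": _checksum(hyd.phi0),
        "K_checksum": _checksum(hyd.K),
    }

    # --- catheters / sources -------------------------------------------------
    proto_cfg = cfg["protocol"]
    if cfg["phantom"]["use"]:
        catheters = [
            phantom.default_catheter(
                spec,
                flow_rate=proto_cfg["flow_rate_mL_h"],
                concentration=proto_cfg["infusate_concentration"],
            )
        ]
    else:
        catheters = [
            flow.CatheterSpec(
                tip=tuple(c["tip"]),
                direction=tuple(c.get("direction", (0, 0, 1))),
                backflow_length=c.get("backflow_length", 0.0),
                flow_rate=c.get("flow_rate", proto_cfg["flow_rate_mL_h"]),
                infusate_concentration=c.get(
                    "concentration", proto_cfg["infusate_concentration"]
                ),
            )
            for c in cfg.get("catheters", [])
        ]
    sources = [
        flow.build_source_region(c, grid, hyd.parenchyma_mask) for c in catheters
    ]

    # --- poroelastic flow ----------------------------------------------------
    fcfg = cfg["flow"]
    sol = flow.iterate_poroelastic(
        hyd, sources, alpha, B, max_iter=fcfg["max_iter"], tol=fcfg["tol"]
    )
    io.write_volume(tissue.ScalarField(grid, sol.pressure.values, "Pa"),
                    outdir / "pressure.nii.gz")
    io.write_volume(tissue.ScalarField(grid, sol.hydraulic.phi, "1"),
                    outdir / "phi_final.nii.gz")
    for ax, name in enumerate("xyz"):
        io.write_volume(
            tissue.ScalarField(grid, sol.velocity.values[ax], "mm/s"),
            outdir / f"velocity_{name}.nii.gz",
        )
    pd.DataFrame(
        {
            "iteration": np.arange(1, len(sol.residual_history) + 1),
            "max_rel_dphi": sol.residual_history,
        }
    ).to_csv(outdir / "flow_iterations.csv", index=False)
    log["stages"]["flow"] = {
        "iterations": sol.iterations,
        "converged": sol.converged,
        "conservation_error": sol.diagnostics.conservation_error,
        "pressure_checksum": _checksum(sol.pressure.values),
    }

    # --- loss-rate field -----------------------------------------------------
    tr_cfg = cfg["transport"]
    if tr_cfg.get("uniform_loss") is not None:
        loss = np.where(hyd.parenchyma_mask, float(tr_cfg["uniform_loss"]), 0.0)
    elif ktrans_field is not None:
        loss = dce.ktrans_to_loss_rate(
            ktrans_field.values,
            molecule=tr_cfg["molecule"],
            coverage_mask=coverage,
            default_rate=cfg["dce"]["normal_loss_rate"],
        )
        loss = np.where(hyd.parenchyma_mask, loss, 0.0)
    else:
        loss = np.where(hyd.parenchyma_mask, cfg["dce"]["normal_loss_rate"], 0.0)

    D = transport.drug_diffusivity(
        tr_cfg["water_diffusivity"], tr_cfg["molecular_weight_ratio"]
    )
    params = transport.TransportParams(D=D, loss_rate=loss)

    protocol = transport.InfusionProtocol(
        catheters=catheters,
        duration=proto_cfg["duration_h"],
        snapshot_times=list(proto_cfg["snapshot_times_h"]),
    )
    result = transport.run_infusion(
        protocol, sol, params, grid,
        diffusion_off=tr_cfg.get("diffusion_off", False),
    )
    for snap, t_h in zip(result.snapshots, protocol.snapshot_times):
        io.write_volume(
            tissue.ScalarField(grid, snap.c, "infusate"),
            outdir / f"c_{t_h:g}h.nii.gz",
        )
    pd.DataFrame(result.ledger_history).to_csv(outdir / "mass_ledger.csv", index=False)
    log["stages"]["transport"] = {
        "n_steps": result.n_steps,
        "dt_s": result.dt,
        "ledger": result.ledger.as_dict(),
        "final_checksum": _checksum(result.final.c),
    }

    # --- quantify ------------------------------------------------------------
    qcfg = cfg["quantify"]
    threshold = qcfg["threshold_fraction"] * proto_cfg["infusate_concentration"]
    rows = []
    for snap, t_h in zip(result.snapshots, protocol.snapshot_times):
        vi = sum(c.flow_rate for c in catheters) * min(t_h, protocol.duration)
        rep = quantify.compute_vd(
            snap.c, threshold, grid, tumor_mask=tumor_mask, infused_volume_mL=vi
        )
        rows.append(
            {
                "timepoint_h": t_h,
                "Vd_mL": rep.Vd_mL,
                "Vi_mL": vi,
                "Vd_over_Vi": rep.Vd_over_Vi,
                "tumor_coverage_pct": 100.0 * (rep.tumor_coverage or 0.0),
            }
        )
    report = pd.DataFrame(rows)
    report.to_csv(outdir / "vd_report.csv", index=False)
    log["stages"]["quantify"] = {"report": rows, "threshold": threshold}

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=float)
    return log
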