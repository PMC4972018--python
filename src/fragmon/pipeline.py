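"""Configuration-driven orchestration of the full monitoring chain.

A run config (YAML) describes the beam, phantom, emission model, tracker and
analysis settings; ``run_monitor`` executes simulate -> survive -> detect ->
POCA-reconstruct -> histogram -> fit -> observables (and optionally LUT
build + absorption unfolding), writing tabular CSV/JSON artifacts stamped
with the config hash.  All randomness derives from one master seed with one
substream per stage, so changing e.g. the detector smearing does not perturb
the emission sampling.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import transport as tr
from .detection import TrackerSpec, detect, longitudinal_profile, poca_vertex, solid_angle
from .emission import (
    EmissionModel,
    sample_tracks,
    scatter_direction,
    survival_probability,
    tracks_to_dataframe,
)
from .geometry import Box, Cylinder, Phantom, Ray, Region, Sphere, exit_path_thickness
from .profiles import beam_spot_sigma, fit_profile, range_observables
from .transport import BeamSpec, get_material, get_particle
from .unfolding import AbsorptionLUT, build_lut, unfold_profile

logger = logging.getLogger(__name__)

__all__ = [
    "load_config",
    "validate_config",
    "build_beam",
    "build_phantom",
    "build_tracker",
    "build_emission_model",
    "run_chain",
    "run_monitor",
    "config_hash",
]

_STAGES = ("emission", "survival", "scatter", "detect", "lut")


def load_config(path) -> dict:
    with open(path) as fh:
        try:
            cfg = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValueError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _solid_from_config(spec: dict):
    kind = spec.get("type")
    if kind == "sphere":
        return Sphere(tuple(spec["center"]), float(spec["radius"]))
    if kind == "box":
        return Box(tuple(spec["center"]), tuple(spec["size"]))
    if kind == "cylinder":
        return Cylinder(tuple(spec["center"]), tuple(spec["axis"]),
                        float(spec["radius"]), float(spec["length"]))
    raise ValueError(f"unknown solid type {kind!r}")


def build_phantom(cfg: dict) -> Phantom:
    regions = []
    for rc in cfg["regions"]:
        regions.append(
            Region(
                solid=_solid_from_config(rc["solid"]),
                material=get_material(rc.get("material", "pmma")),
                density_override=rc.get("density"),
            )
        )
    return Phantom(tuple(regions))


def build_beam(cfg: dict) -> BeamSpec:
    return BeamSpec(
        particle=get_particle(cfg.get("particle", "12C")),
        E_u=float(cfg["E_u"]),
        entry_point=tuple(cfg.get("entry_point", (0.0, 0.0, 0.0))),
        direction=tuple(cfg.get("direction", (0.0, 0.0, 1.0))),
        sigma_beam=float(cfg.get("sigma_beam", 0.0)),
    )


def build_tracker(cfg: dict) -> TrackerSpec:
    return TrackerSpec(
        theta=float(cfg.get("theta", 90.0)),
        distance=float(cfg.get("distance", 40.0)),
        a=float(cfg.get("a", 20.0)),
        b=float(cfg.get("b", 20.0)),
        angular_sigma=float(cfg.get("angular_sigma", 0.0)),
        point_sigma=float(cfg.get("point_sigma", 0.0)),
        efficiency=float(cfg.get("efficiency", 1.0)),
        reference=tuple(cfg.get("reference", (0.0, 0.0, 0.0))),
    )


def build_emission_model(cfg: dict | None) -> EmissionModel:
    cfg = dict(cfg or {})
    if "species" in cfg:
        cfg["species"] = get_particle(cfg["species"])
    if "yields" in cfg:
        cfg["yields"] = {float(k): float(v) for k, v in cfg["yields"].items()}
    return EmissionModel(**cfg)


def validate_config(cfg: dict) -> list[str]:
    """Schema and physics-sanity findings; an empty list means valid."""
    findings: list[str] = []
    for key in ("beam", "phantom", "tracker"):
        if key not in cfg:
            findings.append(f"missing required section '{key}'")
    if findings:
        return findings
    try:
        beam = build_beam(cfg["beam"])
        if not (tr.E_U_MIN <= beam.E_u <= tr.E_U_MAX):
            findings.append(
                f"beam energy {beam.E_u} MeV/u outside the transport validity "
                f"range [{tr.E_U_MIN}, {tr.E_U_MAX}] MeV/u"
            )
    except Exception as exc:
        findings.append(f"beam: {exc}")
        beam = None
    try:
        phantom = build_phantom(cfg["phantom"])
    except Exception as exc:
        findings.append(f"phantom: {exc}")
        phantom = None
    try:
        tracker_cfg = dict(cfg["tracker"])
        theta = float(tracker_cfg.get("theta", 90.0))
        if not (0.0 < theta < 180.0):
            findings.append(
                f"tracker theta = {theta} deg: the beam-spot term "
                "sigma_beam x cot(theta) diverges at 0/180 deg"
            )
        else:
            build_tracker(tracker_cfg)
    except Exception as exc:
        findings.append(f"tracker: {exc}")
    try:
        build_emission_model(cfg.get("emission"))
    except Exception as exc:
        findings.append(f"emission: {exc}")
    if "seed" not in cfg:
        findings.append("missing explicit 'seed' (wall-clock seeding is not allowed)")
    if beam is not None and phantom is not None:
        try:
            ray = Ray(tuple(beam.entry_point), tuple(beam.direction))
            from .geometry import chord_lengths

            if not chord_lengths(ray, phantom):
                findings.append("beam axis does not intersect the phantom")
        except Exception as exc:
            findings.append(f"beam/phantom geometry: {exc}")
        unf = cfg.get("unfolding") or {}
        if unf.get("enabled") and unf.get("thicknesses") and unf.get("mode", "raise") == "raise":
            x_probe = _max_exit_thickness(beam, phantom, cfg)
            span_hi = max(float(t) for t in unf["thicknesses"])
            if x_probe > span_hi:
                findings.append(
                    f"phantom exit thickness up to {x_probe:.1f} cm exceeds the "
                    f"LUT span (max {span_hi} cm); weighting would extrapolate"
                )
    return findings


def _max_exit_thickness(beam, phantom, cfg) -> float:
    from .emission import emission_density

    tracker = build_tracker(cfg["tracker"])
    model = build_emission_model(cfg.get("emission"))
    density = emission_density(beam, phantom, model)
    d = np.asarray(beam.direction, dtype=float)
    base = np.asarray(beam.entry_point, dtype=float)
    u0 = float(np.dot(base, d))
    x_max = 0.0
    for u in np.linspace(density.u_entry + 1e-6, density.u_stop - 1e-6, 40):
        v = base + (u - u0) * d
        if not phantom.contains(v):
            continue
        x_max = max(x_max, exit_path_thickness(v, tuple(tracker.axis), phantom))
    return x_max


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(s) for name, s in zip(_STAGES, children)}


def run_chain(
    beam: BeamSpec,
    phantom: Phantom,
    model: EmissionModel,
    tracker: TrackerSpec,
    n_tracks: int,
    seed: int,
    multiple_scattering: bool = True,
    sample_survival: bool = False,
) -> dict:
    """Simulate and reconstruct one detected-track sample.

    Returns a dict with the emitted tracks, per-track survival weights and
    exit thicknesses, the detected tracks, and the POCA emission-point
    estimates (``z_reco`` is the beam-axis projection; ``x_exit`` the exit
    WET of the matching emitted track).  By default survival enters as a
    statistical weight; with ``sample_survival`` it is a Bernoulli decision
    and every detected track has unit weight (matching counting statistics
    of real tracked samples).
    """
    rngs = _stage_rngs(seed)
    tracks = sample_tracks(beam, phantom, model, n_tracks,
                           theta_aim=tracker.theta, seed=rngs["emission"])
    x_exit = np.array(
        [exit_path_thickness(t.vertex, t.direction, phantom) for t in tracks]
    )
    surv = np.array(
        [survival_probability(t, phantom, model, exit_wet=x)
         for t, x in zip(tracks, x_exit)]
    )
    if sample_survival:
        surv = (rngs["survival"].random(len(surv)) < surv).astype(float)
    if multiple_scattering:
        for t, x in zip(tracks, x_exit):
            t.direction = scatter_direction(t, phantom, seed=rngs["scatter"], exit_wet=x)
    detected = detect(tracks, tracker, seed=rngs["detect"], weights=surv)
    beam_point = np.asarray(beam.entry_point, dtype=float)
    beam_dir = np.asarray(beam.direction, dtype=float)
    vertices, docas = [], []
    for d in detected:
        v, doca = poca_vertex(d.point, d.direction, beam_point, beam_dir)
        vertices.append(v)
        docas.append(doca)
    vertices = np.asarray(vertices).reshape(-1, 3)
    z_reco = vertices @ beam_dir if len(vertices) else np.empty(0)
    # exit thickness of the reconstructed track, re-traced from the POCA
    # vertex along the measured direction (the CT-like x of the weighting)
    x_reco = np.array(
        [
            exit_path_thickness(v, tuple(d.direction), phantom)
            if phantom.contains(v) else np.nan
            for v, d in zip(vertices, detected)
        ]
    )
    return {
        "tracks": tracks,
        "survival": surv,
        "x_exit": x_exit,
        "detected": detected,
        "poca_points": vertices,
        "doca": np.asarray(docas),
        "z_reco": np.asarray(z_reco),
        "x_reco": x_reco,
        "weights": np.array([d.weight for d in detected]),
    }


def run_monitor(cfg: dict, output_dir=None) -> dict:
    """Execute the full monitoring chain described by a run config.

    Writes the track table, profile, fit report and (if configured) the LUT
    and unfolded profiles under the output directory; returns the run report.
    Identical config + seed give identical numeric outputs.
    """
    findings = validate_config(cfg)
    if findings:
        raise ValueError("invalid config: " + "; ".join(findings))
    chash = config_hash(cfg)
    out = Path(output_dir or cfg.get("output_dir", "fragmon_out"))
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    beam = build_beam(cfg["beam"])
    phantom = build_phantom(cfg["phantom"])
    tracker = build_tracker(cfg["tracker"])
    model = build_emission_model(cfg.get("emission"))
    analysis = cfg.get("analysis") or {}
    seed = int(cfg["seed"])
    n_tracks = int(analysis.get("n_tracks", 20000))
    bin_width = float(analysis.get("bin_width", 0.2))

    chain = run_chain(beam, phantom, model, tracker, n_tracks, seed,
                      multiple_scattering=bool(analysis.get("multiple_scattering", True)))
    logger.info("simulated %d tracks, detected %d", n_tracks, len(chain["detected"]))

    df = tracks_to_dataframe(chain["tracks"])
    df["survival"] = chain["survival"]
    df["x_exit_cm"] = chain["x_exit"]
    _write_csv(df, out / "tracks.csv", chash)

    det_rows = pd.DataFrame(
        {
            "x_cm": [d.point[0] for d in chain["detected"]],
            "y_cm": [d.point[1] for d in chain["detected"]],
            "z_cm": [d.point[2] for d in chain["detected"]],
            "dx": [d.direction[0] for d in chain["detected"]],
            "dy": [d.direction[1] for d in chain["detected"]],
            "dz": [d.direction[2] for d in chain["detected"]],
            "weight": chain["weights"],
            "poca_x": chain["poca_points"][:, 0],
            "poca_y": chain["poca_points"][:, 1],
            "poca_z": chain["poca_points"][:, 2],
            "doca_cm": chain["doca"],
            "x_reco_cm": chain["x_reco"],
        }
    )
    _write_csv(det_rows, out / "detected.csv", chash)

    from .emission import emission_density

    density = emission_density(beam, phantom, model)
    lo = density.u_entry - 2.0
    hi = density.u_stop + 2.0
    edges = lo + bin_width * np.arange(int(math.ceil((hi - lo) / bin_width)) + 1)
    beam_dir = np.asarray(beam.direction, dtype=float)
    profile = longitudinal_profile(chain["poca_points"], edges,
                                   weights=chain["weights"], axis=beam_dir)
    _write_csv(profile.to_dataframe(), out / "profile.csv", chash)

    conv = analysis.get("conv_sigma", "auto")
    conv_sigma = (
        beam_spot_sigma(beam.sigma_beam, tracker.theta) if conv == "auto" else float(conv)
    )
    params = fit_profile(profile, conv_sigma=conv_sigma, seed=seed)
    obs = range_observables(params)

    report = {
        "config_hash": chash,
        "seed": seed,
        "n_tracks": n_tracks,
        "n_detected": len(chain["detected"]),
        "solid_angle_sr": solid_angle(tracker),
        "delta_beam_cm": density.delta_beam,
        "conv_sigma_cm": conv_sigma,
        "fit": {
            "params": {k: float(getattr(params, k))
                       for k in ("p0", "p1", "p2", "p3", "p4", "p5")},
            "chi2": params.chi2,
            "ndf": params.ndf,
        },
        "observables": {
            "delta40_cm": obs.delta40,
            "delta40_err_cm": obs.err_delta40,
            "delta40_tangent_cm": obs.delta40_tangent,
            "delta40_tangent_err_cm": obs.err_delta40_tangent,
            "x_left_cm": obs.x_left,
            "x_left_err_cm": obs.err_x_left,
            "x_right_cm": obs.x_right,
        },
        "warnings": [],
        "elapsed_s": None,
    }

    unf = cfg.get("unfolding") or {}
    if unf.get("enabled"):
        mode = unf.get("mode", "raise")
        lut_seed = int(np.random.SeedSequence(seed).spawn(len(_STAGES))[-1].entropy) % (2**31)
        lut = build_lut(
            beam, phantom, tracker, model,
            thicknesses=unf.get("thicknesses", (2.5, 4.0, 5.5, 7.0, 8.5, 10.0)),
            n_tracks=int(unf.get("n_tracks", n_tracks)),
            seed=lut_seed,
            degree=int(unf.get("degree", 2)),
            x0=unf.get("x0"),
            edges=edges,
        )
        lut.to_json(out / "lut.json")
        corrected, uncorrected, info = unfold_profile(
            chain["z_reco"], chain["x_reco"], lut, edges,
            weights=chain["weights"], mode=mode,
        )
        _write_csv(corrected.to_dataframe(), out / "profile_unfolded.csv", chash)
        report["unfolding"] = {
            "lut_span_cm": list(lut.span),
            "x0_cm": lut.x0,
            "n_skipped": info["n_skipped"],
            "capped_fraction": info["capped_fraction"],
        }
        if info["capped_fraction"] > 0.01:
            report["warnings"].append(
                f"capped weight fraction {info['capped_fraction']:.3f} exceeds 1%"
            )

    report["elapsed_s"] = round(time.time() - t_start, 3)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _write_csv(df: pd.DataFrame, path: Path, chash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    """Read a fragmon CSV, skipping the config-hash header line."""
    return pd.read_csv(path, comment="#")
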