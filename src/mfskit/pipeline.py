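"""Config-driven end-to-end analysis runs on synthetic or user data.

A pipeline run generates (or loads) structures and trajectories, executes
the enabled analysis stages in dependency order, and writes every artifact
into the output directory together with a manifest of content hashes —
identical config + seed gives identical hashes.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import confspace, core, fes, geometry, interactions, lipids, synthetic
from .structures import AtomRecord, Structure, Trajectory, write_structure

logger = logging.getLogger(__name__)

DEFAULT_STAGES = {
    "pca": True, "tilt": True, "gating": True, "pore": True,
    "hbonds": True, "charge_relay": True, "lipids": True, "fes": True,
}

DEFAULT_PARAMS = {
    "hbond_distance": 3.0,      # Angstrom, donor...acceptor
    "hbond_angle": 135.0,       # degrees, D-H...A
    "contact_cutoff": 4.0,      # Angstrom
    "fraction_threshold": 0.1,
    "fes_grid": [80, 80],
    "gmm_k_min": 2,
    "gmm_k_max": 16,
    "gmm_restarts": 5,
    "points_per_tmh": 20,
    "hotspot_threshold": 0.8,
    "lipid_cutoff": 4.0,
    "pore_z_step": 1.0,
    "pore_snapshots": 3,   # demo preset; pore_radius_profile itself defaults to 500
    "classify_margin": 0.1,
    "gate_segment": 8,
    "n_components": 2,
}

DEFAULT_SYNTHETIC = {
    "bundle": {
        "n_helices": 12, "residues_per_helix": 24, "bundle_radius": 18.0,
        "tilt_deg": 30.0, "rise_per_residue": 1.5,
    },
    "ensembles": {"n_per_state": 20, "noise_sigma": 0.3},
    "trajectory": {
        "gate_levels": [0.0, 4.0, 8.0],
        "frames_per_level": 100,
        "noise_sigma": 0.5,
    },
    "membrane": {
        "composition": {"PC": 0.5, "PE": 0.25, "CHL": 0.25},
        "lipids_per_leaflet": 64, "box_xy": 120.0, "n_frames": 25,
    },
}


class ConfigError(ValueError):
    pass


def _deep_merge(defaults: dict, override: dict) -> dict:
    out = copy.deepcopy(defaults)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class PipelineConfig:
    seed: int
    outdir: str = "mfskit_out"
    stages: dict = field(default_factory=lambda: dict(DEFAULT_STAGES))
    params: dict = field(default_factory=lambda: dict(DEFAULT_PARAMS))
    synthetic: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_SYNTHETIC))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "outdir": self.outdir,
            "stages": copy.deepcopy(self.stages),
            "params": copy.deepcopy(self.params),
            "synthetic": copy.deepcopy(self.synthetic),
        }


def validate_config(source) -> PipelineConfig:
    """Validate and fully default a pipeline config (path, YAML string or
    mapping).  Raises :class:`ConfigError` naming the missing field/stage."""
    if isinstance(source, PipelineConfig):
        raw = source.to_dict()
    elif isinstance(source, dict):
        raw = source
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    stages = _deep_merge(DEFAULT_STAGES, raw.get("stages", {}))
    params = _deep_merge(DEFAULT_PARAMS, raw.get("params", {}))
    synth = _deep_merge(DEFAULT_SYNTHETIC, raw.get("synthetic", {}))
    for name in stages:
        if name not in DEFAULT_STAGES:
            raise ConfigError(f"unknown stage {name!r}")
    if stages.get("fes"):
        if not (stages.get("pca") and stages.get("gating")):
            raise ConfigError(
                "stage 'fes' needs its collective-variable inputs: enable "
                "stages 'pca' and 'gating'")
    stochastic = any(stages.values())
    seed = raw.get("seed")
    if seed is None and stochastic:
        raise ConfigError("field 'seed' is required when any stochastic "
                          "stage is enabled")
    return PipelineConfig(
        seed=int(seed if seed is not None else 0),
        outdir=str(raw.get("outdir", "mfskit_out")),
        stages=stages, params=params, synthetic=synth,
    )


def merge_structures(protein: Structure, other: Structure) -> Structure:
    """Concatenate two structures, renumbering serials and offsetting the
    second structure's residue ids past the first's."""
    offset = max(a.residue_id for a in protein.atoms)
    atoms = list(protein.atoms)
    serial = len(atoms)
    for a in other.atoms:
        serial += 1
        atoms.append(AtomRecord(
            serial=serial, name=a.name, element=a.element,
            residue_name=a.residue_name, residue_id=a.residue_id + offset,
            chain=a.chain, is_protein=a.is_protein, vdw_radius=a.vdw_radius))
    coords = np.vstack([protein.coords, other.coords])
    return Structure(atoms=atoms, coords=coords, box=protein.box)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def run_pipeline(config: PipelineConfig, only_stages=None) -> dict:
    """Execute enabled stages in dependency order; returns the manifest
    (file -> sha256), which is also written to ``outdir/manifest.json``."""
    cfg = validate_config(config)
    if only_stages is not None:
        cfg.stages = {k: (k in only_stages) for k in cfg.stages}
        cfg = validate_config(cfg)
    os.makedirs(cfg.outdir, exist_ok=True)
    p = cfg.params
    outputs: list[str] = []

    def out(name: str) -> str:
        path = os.path.join(cfg.outdir, name)
        outputs.append(path)
        return path

    echo = out("effective_config.yaml")
    with open(echo, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)

    def stage(name):
        enabled = cfg.stages.get(name, False)
        if enabled:
            logger.info("stage %s: start", name)
        return enabled

    t0 = time.time()
    bspec = synthetic.BundleSpec(seed=cfg.seed, state_param=0.0,
                                 **cfg.synthetic["bundle"])
    of_bundle, cmap = synthetic.build_two_state_bundle(bspec)
    write_structure(of_bundle, out("bundle_of.pdb"))
    core.save_core_map({"bundle": cmap}, out("core_map.yaml"))

    traj = None
    projections = None
    gate_dist = None
    space = None

    needs_traj = any(cfg.stages.get(s) for s in
                     ("pca", "tilt", "gating", "pore", "fes"))
    if needs_traj:
        tcfg = cfg.synthetic["trajectory"]
        schedule = np.repeat(np.asarray(tcfg["gate_levels"], dtype=float),
                             tcfg["frames_per_level"])
        traj = synthetic.generate_gating_trajectory(synthetic.GatingTrajectorySpec(
            bundle=bspec, gate_schedule=schedule,
            noise_sigma=tcfg["noise_sigma"], seed=cfg.seed + 2))

    if stage("pca"):
        ecfg = cfg.synthetic["ensembles"]
        of_spec = synthetic.BundleSpec(seed=cfg.seed, state_param=0.0,
                                       **cfg.synthetic["bundle"])
        if_spec = synthetic.BundleSpec(seed=cfg.seed + 1, state_param=1.0,
                                       **cfg.synthetic["bundle"])
        ofs = synthetic.generate_state_ensemble(of_spec, ecfg["n_per_state"],
                                                ecfg["noise_sigma"])
        ifs = synthetic.generate_state_ensemble(if_spec, ecfg["n_per_state"],
                                                ecfg["noise_sigma"])
        labels = ["OF"] * len(ofs) + ["IF"] * len(ifs)
        space = confspace.fit_space_from_structures(
            ofs + ifs, labels, cmap, n_components=p["n_components"],
            points_per_tmh=p["points_per_tmh"])
        confspace.save_space(space, out("conformational_space.npz"))
        projections = confspace.project_frames(traj, cmap, space)
        states = [confspace.classify_state(pc, space, p["classify_margin"])
                  for pc in projections.coordinates]
        df = pd.DataFrame(projections.coordinates,
                          columns=[f"PC{i+1}" for i in range(projections.n_components)])
        df.insert(0, "frame", np.arange(traj.n_frames))
        df["state"] = states
        _write_csv(df, out("projections.csv"))

    if stage("tilt"):
        prof = geometry.tilt_profile(traj, cmap)
        df = pd.DataFrame({
            "tmh": np.arange(1, len(prof.mean_tilt) + 1),
            "mean_tilt_deg": prof.mean_tilt,
            "sd_tilt_deg": prof.sd_tilt,
        })
        _write_csv(df, out("tilt_profile.csv"))

    if stage("gating"):
        sel1 = geometry.gate_selection(traj.topology, cmap, tmh=1,
                                       n_res=p["gate_segment"])
        sel7 = geometry.gate_selection(traj.topology, cmap,
                                       tmh=1 + bspec.n_helices // 2,
                                       n_res=p["gate_segment"])
        gate_dist = geometry.pairwise_com_distance(traj, sel1, sel7)
        df = pd.DataFrame({"frame": np.arange(traj.n_frames),
                           "gate_distance_A": gate_dist})
        _write_csv(df, out("gating_distance.csv"))

    if stage("pore"):
        prof = geometry.pore_radius_profile(
            traj, z_step=p["pore_z_step"],
            n_snapshots=p["pore_snapshots"],
            search_radius=10.0, cap=20.0)
        df = pd.DataFrame({"z_A": prof.z, "mean_radius_A": prof.mean_radius,
                           "sd_radius_A": prof.sd_radius,
                           "capped": prof.capped.astype(int)})
        _write_csv(df, out("pore_profile.csv"))

    table = None
    if stage("hbonds"):
        hb_traj, donors, acceptors = synthetic.build_charge_relay_fixture()
        criteria = interactions.HBondCriteria(p["hbond_distance"],
                                              p["hbond_angle"])
        table = interactions.interaction_fractions(
            hb_traj, donors, acceptors, criteria,
            threshold=p["fraction_threshold"])
        interactions.write_fraction_table_tsv(table, out("hbond_fractions.tsv"))

    if stage("charge_relay"):
        if table is None:
            raise ConfigError("stage 'charge_relay' needs stage 'hbonds'")
        seq = synthetic.synthetic_transporter_sequence()
        hits = core.motif_scan(seq)
        # keep the annotated triad hits (one per motif per bundle)
        wanted = {name: start for name, (start, _) in
                  synthetic.MOTIF_ANNOTATION.items()}
        triad_hits = [h for h in hits
                      if wanted.get(h.pattern_name) == h.start]
        # the C-bundle A-motif diverges from the canonical pattern; anchor
        # on its conserved LGRR tail instead
        if not any(h.pattern_name == "A-motif/C" for h in triad_hits):
            lgrr = [h for h in core.motif_scan(seq, [core.LGRR_ANCHOR])
                    if h.start >= wanted["PETL/N"]]
            if lgrr:
                h = lgrr[0]
                triad_hits.append(core.MotifHit("A-motif/C", h.start,
                                                h.end, h.matched))
        report = interactions.charge_relay_summary(table, triad_hits)
        with open(out("charge_relay.json"), "w") as fh:
            json.dump({
                "triads": {b: {m: list(r) for m, r in ms.items()}
                           for b, ms in report.triads.items()},
                "intra_bundle": _jsonable(report.intra_bundle),
                "inter_bundle": _jsonable(report.inter_bundle),
                "tmh_extensions": _jsonable(report.tmh_extensions),
            }, fh, indent=2)

    if stage("lipids"):
        mcfg = cfg.synthetic["membrane"]
        mspec = synthetic.MembranePatchSpec(
            composition=mcfg["composition"],
            lipids_per_leaflet=mcfg["lipids_per_leaflet"],
            box_xy=mcfg["box_xy"], seed=cfg.seed + 3)
        mtraj = synthetic.generate_membrane_trajectory(mspec, mcfg["n_frames"])
        combined_top = merge_structures(of_bundle, mtraj.topology)
        prot_frames = np.repeat(of_bundle.coords[None], mtraj.n_frames, axis=0)
        frames = np.concatenate([prot_frames, mtraj.frames], axis=1)
        # center the membrane box on the protein
        frames[:, of_bundle.n_atoms:, 0] -= mcfg["box_xy"] / 2.0
        frames[:, of_bundle.n_atoms:, 1] -= mcfg["box_xy"] / 2.0
        ctraj = Trajectory(topology=combined_top, frames=frames)
        profile = lipids.residue_lipid_occupancy(ctraj,
                                                 cutoff=p["lipid_cutoff"])
        lipids.write_occupancy_tsv(profile, out("lipid_occupancy.tsv"))
        hotspots = lipids.hotspot_residues(profile, p["hotspot_threshold"])
        with open(out("lipid_hotspots.tsv"), "w") as fh:
            fh.write("residue\tlipid_type\tfraction\n")
            for r, t, f in hotspots.residues:
                fh.write(f"{r}\t{t}\t{f:.4f}\n")
        for leaflet in ("upper", "lower"):
            maps = lipids.leaflet_density_map(ctraj, leaflet=leaflet)
            for t, m in maps.items():
                path = out(f"density_{leaflet}_{t}.txt")
                with open(path, "w") as fh:
                    fh.write(f"# leaflet {leaflet} type {t} "
                             f"empty {int(m['empty'])}\n")
                    fh.write("# xedges " + " ".join(
                        f"{x:.3f}" for x in m["xedges"]) + "\n")
                    fh.write("# yedges " + " ".join(
                        f"{y:.3f}" for y in m["yedges"]) + "\n")
                    for row in m["histogram"]:
                        fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")

    if stage("fes"):
        cv = np.column_stack([projections.coordinates[:, 0], gate_dist])
        model = fes.fit_density_model(
            cv, k_range=range(p["gmm_k_min"], p["gmm_k_max"] + 1),
            n_restarts=p["gmm_restarts"], seed=cfg.seed)
        pad = 0.05 * (cv.max(axis=0) - cv.min(axis=0))
        ranges = [(cv[:, d].min() - pad[d], cv[:, d].max() + pad[d])
                  for d in range(2)]
        grid = fes.free_energy_surface(model, ranges,
                                       grid_shape=tuple(p["fes_grid"]))
        basins = fes.extract_basins(grid)
        assign = fes.assign_clusters_and_populations(cv, grid, basins)
        fes.write_fes_grid(grid, out("fes_grid.txt"))
        df = pd.DataFrame({
            "frame": np.arange(len(cv)), "PC1": cv[:, 0],
            "gate_distance_A": cv[:, 1], "basin": assign.sample_labels,
        })
        _write_csv(df, out("fes_assignments.csv"))
        pops = pd.DataFrame(
            sorted(assign.populations.items()),
            columns=["basin", "population"])
        _write_csv(pops, out("basin_populations.csv"))

    manifest = {os.path.relpath(f, cfg.outdir): _sha256(f) for f in outputs}
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline done in %.1f s (%d files)",
                time.time() - t0, len(manifest))
    return manifest


def _jsonable(entries: list[dict]) -> list[dict]:
    out = []
    for e in entries:
        out.append({
            "residues": list(e["residues"]),
            "fraction": round(float(e["fraction"]), 6),
            "salt_bridge": e["salt_bridge"],
            "motifs": [list(m) if m else None for m in e["motifs"]],
        })
    return out
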