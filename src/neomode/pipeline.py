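"""End-to-end orchestration: one config, deterministic seeds, manifest I/O.

Stages run in method order — geometry, eigenmodes, cohort simulation,
edge-reliability mask, connectivity, network statistics, (optional)
spectral fingerprints, mode-weight fitting, group statistics and
brain-behavior coupling — each writing its outputs under the configured
directory with a stage manifest (parameter hash, seed, wall time).  An
unchanged stage whose outputs are present is loaded instead of recomputed;
because every random draw is derived from the master seed, recomputing a
deleted stage reproduces its outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import eigenmodes as em
from . import inference_stats as infs
from . import netstats as ns
from . import neural_field_model as nfm
from . import signal_filters as sf
from . import synthetic_data as sd

__all__ = ["PipelineConfig", "RunManifest", "validate_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on.

    The default is a desk-scale demo design (12 subjects per group, 60 s
    records); ``PipelineConfig.paper_scale()`` returns the full-size design
    (42 + 52 subjects, 300 s, 5000 permutations, 500 mask iterations).
    """

    out_dir: str = "neomode_out"
    seed: int = 0
    # geometry
    lobe_semi_axes: tuple = (60.0, 45.0, 40.0)
    gap_mm: float = 6.0
    subdivisions: int = 3
    n_parcel_pairs: int = 29
    n_modes: int = 6
    # cohort
    n_per_group: dict = field(default_factory=lambda: {"EP": 12, "HC": 12})
    duration_s: float = 60.0
    fs_hz: float = 100.0
    mode_weight_means: dict = field(
        default_factory=lambda: dict(sd.DEFAULT_MODE_WEIGHT_MEANS))
    mode_weight_sd: tuple = sd.DEFAULT_MODE_WEIGHT_SD
    noise_sd: float = 1.0
    # connectivity
    band: str = "alpha"
    orthogonalize: bool = False   # synthetic parcels carry no leakage
    window_s: float = 2.0
    # reliability mask
    mask_enabled: bool = True
    leak_spread_mm: float = 25.0
    mask_n_iter: int = 25
    mask_percentile: float = 99.0
    mask_duration_s: float = 20.0
    # network statistics
    nbs_threshold: float = 3.0
    n_permutations: int = 1000
    alpha: float = 0.05
    contrasts: tuple = ("sleep_main", "group_main", "interaction")
    # spectral fingerprint
    fingerprint_enabled: bool = False
    fingerprint_threshold: float = 2.5
    fingerprint_contrast: str = "sleep_main"
    # mode-weight fit
    fit_enabled: bool = True
    grid_step: float = 0.02
    grid_lo: float = 0.0
    grid_hi: float = 0.5
    refine_step: float = 0.0025
    refine_half: float = 0.02
    table_n_u: int = 26
    table_u_max: float = 2.5
    table_n_reps: int = 12
    # outcomes
    outcome_coupling: float = -0.5
    outcome_target_r: float = -0.5
    write_timeseries: bool = False

    @classmethod
    def paper_scale(cls, **overrides) -> "PipelineConfig":
        base = dict(n_per_group={"EP": 42, "HC": 52}, duration_s=300.0,
                    n_permutations=5000, mask_n_iter=500,
                    mask_duration_s=30.0)
        base.update(overrides)
        return cls(**base)

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["mode_weight_means"] = {f"{g}/{s}": list(v) for (g, s), v
                                  in self.mode_weight_means.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "mode_weight_means" in d:
            d["mode_weight_means"] = {
                tuple(k.split("/")): tuple(v)
                for k, v in d["mode_weight_means"].items()}
        for key in ("lobe_semi_axes", "contrasts", "mode_weight_sd"):
            if key in d and isinstance(d[key], (list, tuple)):
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            if path.endswith((".yaml", ".yml")):
                import yaml
                yaml.safe_dump(self.to_dict(), fh)
            else:
                json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            if path.endswith((".yaml", ".yml")):
                import yaml
                return cls.from_dict(yaml.safe_load(fh))
            return cls.from_dict(json.load(fh))

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> list:
    """Rule violations as human-readable strings; empty list means valid."""
    v = []
    if any(n <= 0 for n in config.n_per_group.values()):
        v.append("n_per_group: subject counts must be positive")
    n_samp = config.duration_s * config.fs_hz
    if abs(n_samp - round(n_samp)) > 1e-9:
        v.append("duration_s x fs_hz must be integral")
    if config.fs_hz <= 2 * 13.0:
        v.append("fs_hz: must exceed twice the alpha-band upper edge")
    for (g, s), trip in config.mode_weight_means.items():
        if any(a < 0 for a in trip):
            v.append(f"mode_weight_means[{g}/{s}]: weights must be >= 0")
    if config.band not in sf.CANONICAL_BANDS:
        v.append(f"band: unknown canonical band {config.band!r}")
    bank = sf.build_carrier_bank()
    if bank[0].f <= 0:
        v.append("filter bank: carrier f1 must be positive")
    if config.nbs_threshold <= 0:
        v.append("nbs_threshold: must be positive")
    if config.n_permutations < 100:
        v.append("n_permutations: at least 100 required")
    if not 0 < config.alpha < 1:
        v.append("alpha: must lie in (0, 1)")
    if config.mask_enabled and config.mask_n_iter < 2:
        v.append("mask_n_iter: at least 2 iterations required")
    if config.grid_hi > 0.5 + 1e-12:
        v.append("grid_hi: admissible mode-weight range is 0-0.5")
    if config.grid_lo < 0 or config.grid_lo >= config.grid_hi:
        v.append("grid_lo: must satisfy 0 <= lo < hi")
    for kind in config.contrasts:
        if kind not in ns.CONTRAST_KINDS:
            v.append(f"contrasts: unknown contrast {kind!r}")
    return v


@dataclass
class RunManifest:
    stages: list = field(default_factory=list)

    def record(self, name, t0, seed, outputs, cached=False, **extra):
        self.stages.append({"stage": name, "wall_s": round(time.time() - t0, 3),
                            "seed": seed, "outputs": outputs,
                            "cached": cached, **extra})

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            for rec in self.stages:
                fh.write(json.dumps(rec, default=str) + "\n")


def _stage_seed(master: int, name: str) -> int:
    h = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


class _Stage:
    """Hash-guarded stage: load cached outputs or recompute and persist."""

    def __init__(self, run_dir: str, cfg_hash: str, manifest: RunManifest):
        self.run_dir = run_dir
        self.cfg_hash = cfg_hash
        self.manifest = manifest

    def path(self, *names):
        return [os.path.join(self.run_dir, n) for n in names]

    def run(self, name, outputs, compute, load, seed=None):
        paths = self.path(*outputs)
        marker = os.path.join(self.run_dir, f".{name}.stage.json")
        t0 = time.time()
        if os.path.exists(marker) and all(os.path.exists(p) for p in paths):
            with open(marker) as fh:
                meta = json.load(fh)
            if meta.get("hash") == self.cfg_hash:
                result = load(*paths)
                self.manifest.record(name, t0, seed, outputs, cached=True)
                return result
        result = compute(*paths)
        with open(marker, "w") as fh:
            json.dump({"hash": self.cfg_hash, "stage": name}, fh)
        self.manifest.record(name, t0, seed, outputs, cached=False)
        return result


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis; returns the run manifest.

    Raises on invalid configs; any stage failure propagates with the stage
    name attached.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = RunManifest()
    cfg_hash = config.content_hash()
    stage = _Stage(config.out_dir, cfg_hash, manifest)
    config.save(os.path.join(config.out_dir, "config.json"))

    try:
        return _run_stages(config, stage, manifest)
    except Exception:
        manifest.save(os.path.join(config.out_dir, "manifest.jsonl"))
        raise


def _run_stages(config: PipelineConfig, stage: _Stage,
                manifest: RunManifest) -> RunManifest:
    out = config.out_dir

    # -- geometry ----------------------------------------------------------
    def compute_geometry(mesh_p, parc_p, meta_p):
        mesh = sd.make_bihemispheric_mesh(config.lobe_semi_axes,
                                          config.gap_mm, config.subdivisions)
        parc = sd.make_symmetric_parcellation(mesh, config.n_parcel_pairs)
        mesh.save(mesh_p)
        parc.save(parc_p, meta_p)
        return mesh, parc

    def load_geometry(mesh_p, parc_p, meta_p):
        mesh = sd.SurfaceMesh.load(mesh_p, rebuild_mirror_map=True)
        return mesh, sd.Parcellation.load(parc_p, meta_p)

    mesh, parc = stage.run("geometry",
                           ["mesh.ply", "parcellation.tsv", "parcellation.json"],
                           compute_geometry, load_geometry)

    # -- eigenmodes --------------------------------------------------------
    def compute_modes(basis_p):
        op = em.assemble_laplace_beltrami(mesh)
        basis = em.solve_eigenmodes(op, config.n_modes)
        basis = em.classify_symmetry(basis, mesh)
        basis.mesh_checksum = em.mesh_checksum(mesh)
        basis.save(basis_p)
        return basis

    basis = stage.run("eigenmodes", ["basis.h5"], compute_modes,
                      lambda p: em.EigenmodeBasis.load(p))

    W = em.parcel_weight_matrix(parc, basis.vertex_areas)
    parcel_modes = nfm.unit_rms_parcel_modes(basis, W)

    # -- cohort ------------------------------------------------------------
    cohort_seed = _stage_seed(config.seed, "cohort")
    spec = sd.CohortSpec(n_per_group=dict(config.n_per_group),
                         mode_weight_means=dict(config.mode_weight_means),
                         mode_weight_sd=config.mode_weight_sd,
                         noise_sd=config.noise_sd,
                         duration=config.duration_s, fs=config.fs_hz,
                         seed=cohort_seed)

    def compute_cohort(manifest_p, ts_p):
        cohort = sd.simulate_cohort(spec, basis, parc)
        cohort.manifest().to_csv(manifest_p, sep="\t", index=False)
        arrays = {f"{s.subject}__{st}": s.timeseries[st]
                  for s in cohort.subjects for st in s.timeseries}
        np.savez(ts_p, **arrays)
        if config.write_timeseries:
            cohort.save(os.path.join(out, "cohort"))
        return cohort

    def load_cohort(manifest_p, ts_p):
        man = pd.read_csv(manifest_p, sep="\t")
        data = np.load(ts_p)
        subjects = []
        for subj, dfsub in man.groupby("subject", sort=False):
            row = dfsub.iloc[0]
            ts = {st: data[f"{subj}__{st}"] for st in dfsub["state"]}
            tps = {r["state"]: {"a": (r["true_a1"], r["true_a3"], r["true_a4"]),
                                "sigma": r["true_sigma"]}
                   for _, r in dfsub.iterrows()}
            subjects.append(sd.SubjectRecord(subj, row["group"], row["age"],
                                             ts, tps))
        return sd.CohortDataset(subjects, spec)

    cohort = stage.run("cohort", ["cohort_manifest.tsv", "cohort_ts.npz"],
                       compute_cohort, load_cohort, seed=cohort_seed)

    # -- reliability mask --------------------------------------------------
    mask = None
    if config.mask_enabled:
        mask_seed = _stage_seed(config.seed, "mask")

        def compute_mask(tsv_p, json_p):
            leak = sd.make_toy_leakage_operator(parc, config.leak_spread_mm,
                                                seed=mask_seed)
            m = conn.derive_edge_mask(parc, leak, n_iter=config.mask_n_iter,
                                      percentile=config.mask_percentile,
                                      seed=mask_seed,
                                      duration=config.mask_duration_s,
                                      fs=config.fs_hz,
                                      window_s=config.window_s)
            m.save(tsv_p, json_p)
            return m

        def load_mask(tsv_p, json_p):
            df = pd.read_csv(tsv_p, sep="\t")
            with open(json_p) as fh:
                meta = json.load(fh)
            return conn.EdgeMask(df["retain"].to_numpy(dtype=bool), meta)

        mask = stage.run("mask", ["edge_mask.tsv", "edge_mask.json"],
                         compute_mask, load_mask, seed=mask_seed)

    # -- connectivity ------------------------------------------------------
    band = sf.CANONICAL_BANDS[config.band]

    def compute_connectivity(weights_p, stack_p):
        matrices = {}
        for rec in cohort:
            matrices[rec.subject] = {
                st: conn.connectivity_matrix(
                    rec.timeseries[st], band, config.fs_hz, mask=mask,
                    normalize=True, window_s=config.window_s,
                    orthogonalize=config.orthogonalize,
                    expected_parcels=parc.n_parcels)
                for st in rec.timeseries}
        cc = ns.ConnectivityCohort.from_matrices(
            matrices, {r.subject: r.group for r in cohort},
            parc.n_parcels, mask=mask)
        rows = []
        for si, subj in enumerate(cc.subjects):
            for st_i, st in enumerate(cc.states):
                rows.append(pd.DataFrame({
                    "subject": subj, "state": st,
                    "parcel_i": cc.edge_index[:, 0],
                    "parcel_j": cc.edge_index[:, 1],
                    "weight": cc.weights[si, st_i]}))
        pd.concat(rows).to_csv(weights_p, sep="\t", index=False)
        # lossless copy for bit-identical stage resume
        np.savez(stack_p, weights=cc.weights, groups=cc.groups,
                 edge_index=cc.edge_index,
                 subjects=np.asarray(cc.subjects, dtype="U32"))
        return cc

    def load_connectivity(weights_p, stack_p):
        data = np.load(stack_p)
        return ns.ConnectivityCohort(data["weights"],
                                     data["groups"].astype("U2"),
                                     data["edge_index"], parc.n_parcels,
                                     list(data["subjects"]))

    cc = stage.run("connect", ["edge_weights.tsv", "edge_weights.npz"],
                   compute_connectivity, load_connectivity)

    # -- network statistics ------------------------------------------------
    nbs_results = {}
    for kind in config.contrasts:
        c_seed = _stage_seed(config.seed, f"nbs:{kind}")
        contrast = ns.ContrastSpec(kind=kind, threshold=config.nbs_threshold,
                                   n_permutations=config.n_permutations,
                                   alpha=config.alpha, seed=c_seed)

        def compute_nbs(json_p, _contrast=contrast):
            res = ns.nbs(cc, _contrast)
            res.to_json(json_p)
            return res

        def load_nbs(json_p, _contrast=contrast):
            with open(json_p) as fh:
                d = json.load(fh)
            comps = [ns.NBSComponent(np.asarray(c["edges"]), c["size"],
                                     c["p_fwer"], c["mean_t"], c["sign"])
                     for c in d["components"]]
            null = {int(k): np.asarray(v) for k, v in d["null_max_size"].items()}
            tv = ns.edge_statistics(cc, _contrast)
            return ns.NBSResult(comps, tv, null, _contrast, d["df"])

        nbs_results[kind] = stage.run(f"nbs_{kind}", [f"nbs_{kind}.json"],
                                      compute_nbs, load_nbs, seed=c_seed)

    # -- spectral fingerprint (optional) -----------------------------------
    if config.fingerprint_enabled:
        fp_seed = _stage_seed(config.seed, "fingerprint")

        def compute_fp(tsv_p):
            banks = sf.build_filter_banks()
            contrast = ns.ContrastSpec(kind=config.fingerprint_contrast,
                                       threshold=config.fingerprint_threshold,
                                       n_permutations=config.n_permutations,
                                       alpha=config.alpha, seed=fp_seed)
            grid = ns.spectral_fingerprint(cohort, banks, contrast,
                                           fs=config.fs_hz, mask=mask,
                                           orthogonalize=config.orthogonalize)
            grid.save_tsv(tsv_p)
            return grid

        def load_fp(tsv_p):
            df = pd.read_csv(tsv_p, sep="\t")
            cf = np.unique(df["carrier_hz"])
            af = np.unique(df["amplitude_hz"])
            d = df["cohens_d"].to_numpy().reshape(len(cf), len(af))
            return ns.EffectGrid(d, cf, af)

        stage.run("fingerprint", ["fingerprint.tsv"], compute_fp, load_fp,
                  seed=fp_seed)

    # -- mode-weight fit ---------------------------------------------------
    fits_df = None
    if config.fit_enabled:
        fit_seed = _stage_seed(config.seed, "fit")

        def compute_fit(fits_p, grid_p):
            table = nfm.build_pair_response_table(
                config.table_u_max, config.duration_s, config.fs_hz,
                n_u=config.table_n_u, n_reps=config.table_n_reps,
                seed=fit_seed, band=config.band, window_s=config.window_s)
            ev = nfm.ModelMomentEvaluator(table, parcel_modes,
                                          np.ones(parc.n_parcels), mask=mask)
            axes = nfm.default_grid_axes(config.grid_step, config.grid_lo,
                                         config.grid_hi)
            grid = nfm.precompute_fit_grid(ev, axes,
                                           meta={"seed": fit_seed,
                                                 "pipeline": cfg_fit_hash})
            grid.save(grid_p)
            rows = []
            for rec in cohort:
                for st in rec.timeseries:
                    C = conn.connectivity_matrix(
                        rec.timeseries[st], band, config.fs_hz, mask=mask,
                        normalize=True, window_s=config.window_s,
                        orthogonalize=False,
                        expected_parcels=parc.n_parcels)
                    fit = nfm.fit_subject(C, grid,
                                          refine_step=config.refine_step,
                                          refine_half=config.refine_half,
                                          lo=config.grid_lo, hi=config.grid_hi)
                    fit = nfm.estimate_sigma(fit, rec.timeseries[st],
                                             parcel_modes)
                    rows.append({"subject": rec.subject, "group": rec.group,
                                 "state": st, **fit.as_dict()})
            df = pd.DataFrame(rows)
            df.to_csv(fits_p, sep="\t", index=False)
            return df

        cfg_fit_hash = stage.cfg_hash
        fits_df = stage.run("fit", ["fits.tsv", "fit_grid.h5"], compute_fit,
                            lambda p, g: pd.read_csv(p, sep="\t"),
                            seed=fit_seed)

    # -- group statistics --------------------------------------------------
    def compute_stats(anova_p, asym_p, behav_p):
        if fits_df is not None:
            tables = []
            for col, mode in (("a1_prime", 1), ("a3_prime", 3), ("a4_prime", 4)):
                tab = infs.mixed_anova(
                    fits_df.rename(columns={col: "value"}),
                    dv="value")
                t = tab.as_frame()
                t.insert(0, "mode", mode)
                tables.append(t)
            pd.concat(tables).to_csv(anova_p, sep="\t", index=False)
        else:
            pd.DataFrame().to_csv(anova_p, sep="\t")

        asym = infs.hemispheric_asymmetry(cc, config.n_parcel_pairs)
        asym.table.to_csv(asym_p, sep="\t", index=False)

        inter = nbs_results.get("interaction")
        edge_set = None
        if inter is not None:
            sig = inter.significant()
            big = sig[0] if sig else inter.largest()
            if big is not None:
                edge_set = big.edges
        if edge_set is None:
            edge_set = np.arange(cc.n_edges)
        ep_sel = cc.groups == "EP"
        if ep_sel.sum() < 4:      # partial correlation needs >= 4 subjects
            pd.DataFrame().to_csv(behav_p, sep="\t")
            return None
        change = infs.connectivity_change(cc, edge_set)[ep_sel]
        ep_cohort = sd.CohortDataset([r for r in cohort if r.group == "EP"],
                                     spec)
        # outcome noise set so the planted association lands near the target
        # partial correlation at this cohort's change spread
        r_t = abs(config.outcome_target_r)
        noise_sd = (abs(config.outcome_coupling) * np.std(change)
                    * np.sqrt(max(1.0 / r_t ** 2 - 1.0, 1e-6)))
        outcomes = sd.simulate_outcomes(ep_cohort, change,
                                        coupling=config.outcome_coupling,
                                        noise_sd=float(noise_sd),
                                        seed=_stage_seed(config.seed,
                                                         "outcomes"))
        behav = infs.brain_behavior({config.band: change}, outcomes)
        behav.to_csv(behav_p, sep="\t", index=False)
        return None

    stage.run("stats", ["anova.tsv", "asymmetry.tsv", "behavior.tsv"],
              compute_stats, lambda *p: None)

    manifest.save(os.path.join(out, "manifest.jsonl"))
    return manifest
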