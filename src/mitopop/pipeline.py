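"""Config-driven orchestration of the full analysis battery.

One call runs: haplotype/diversity reports, pairwise PhiST + AMOVA,
the statistical-parsimony network, spatial autocorrelograms + Mantel,
mismatch expansion fits with Fu's FS, and (optionally) the two-deme
isolation-with-migration sampler — each stage writing a TSV into the
output directory, with a JSON manifest recording versions, seeds and
runtimes.  A stage failure is recorded and does not corrupt the outputs
of completed stages.

The global seed is expanded per-stage with a fixed counter scheme
(SeedSequence spawn keys), so disabling one stage does not shift the
random stream of another.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import diversity_table, pairwise_differences
from .imcoal import IMConfig, run_mdiv, summarize_im
from .mismatch import RateModel, fit_demographic, fit_spatial, fu_fs, observed_mismatch
from .network import build_network, write_edge_list
from .seqio import collapse_haplotypes, read_alignment
from .spatial import geo_distances, mantel, spatial_autocorrelogram
from .structure import amova, pairwise_phist

__all__ = ["PipelineConfig", "run_pipeline"]

# fixed spawn keys per stage: toggling a stage never shifts another's stream
STAGE_SEED_KEY = {
    "diversity": 1, "structure": 2, "network": 3, "spatial": 4,
    "mismatch": 5, "im": 6,
}


@dataclass
class PipelineConfig:
    fasta: str
    popmap: str
    coords: str | None = None
    outdir: str = "mitopop_out"
    partitions: dict[str, tuple[int, int]] | None = None
    groups: dict[str, str] | None = None  # deme -> group
    seed: int = 0
    n_perm: int = 10_000
    n_boot_mismatch: int = 1000
    class_size_km: float = 50.0
    confidence: float = 0.95
    u_seq: float = 2e-5
    generation_years: float = 1.0
    run_im: bool = False
    im_pairs: list[tuple[str, str]] = field(default_factory=list)
    im_theta_max: float = 25.0
    im_M_max: float = 10.0
    im_T_max: float = 10.0
    im_steps: int = 4000
    im_chains: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "partitions" in raw and raw["partitions"]:
            raw["partitions"] = {
                k: tuple(v) for k, v in raw["partitions"].items()
            }
        if "im_pairs" in raw and raw["im_pairs"]:
            raw["im_pairs"] = [tuple(p) for p in raw["im_pairs"]]
        return cls(**raw)


def _stage_seed(global_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(global_seed, spawn_key=(STAGE_SEED_KEY[stage],))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_pipeline(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": {},
        "errors": {},
    }
    t_all = time.time()
    aln = read_alignment(cfg.fasta, cfg.popmap, cfg.partitions, cfg.coords)
    if cfg.groups:
        aln.group_of = dict(cfg.groups)
    rate_model = RateModel(u_seq=cfg.u_seq,
                           generation_years=cfg.generation_years)

    def stage(name, fn):
        t0 = time.time()
        try:
            files = fn()
            manifest["stages"][name] = {
                "runtime_s": round(time.time() - t0, 2),
                "files": files,
                "seed": _stage_seed(cfg.seed, name)
                if name in STAGE_SEED_KEY else None,
            }
        except Exception as exc:  # stage isolation by design
            manifest["errors"][name] = f"{type(exc).__name__}: {exc}"
            print(f"[mitopop] stage {name} failed: {exc}", file=sys.stderr)

    def s_diversity():
        table = collapse_haplotypes(aln)
        table.to_frame().to_csv(out / "haplotypes.tsv", sep="\t")
        diversity_table(aln).to_csv(out / "diversity.tsv", sep="\t",
                                    index=False)
        return ["haplotypes.tsv", "diversity.tsv"]

    def s_structure():
        seed = _stage_seed(cfg.seed, "structure")
        ph = pairwise_phist(aln, n_perm=cfg.n_perm, seed=seed)
        ph.phist.round(4).to_csv(out / "phist.tsv", sep="\t")
        ph.pvals.round(5).to_csv(out / "phist_pvals.tsv", sep="\t")
        res = amova(aln, n_perm=cfg.n_perm, seed=seed)
        frames = [res.to_frame().assign(design="one-level")]
        if aln.group_of:
            res2 = amova(aln, grouping=aln.group_of, n_perm=cfg.n_perm,
                         seed=seed)
            frames.append(res2.to_frame().assign(design="two-level"))
        pd.concat(frames).to_csv(out / "amova.tsv", sep="\t", index=False)
        return ["phist.tsv", "phist_pvals.tsv", "amova.tsv"]

    def s_network():
        table = collapse_haplotypes(aln)
        net = build_network(table, L=aln.L, confidence=cfg.confidence)
        write_edge_list(net, out / "network_edges.tsv")
        with open(out / "network_summary.json", "w") as fh:
            json.dump(
                {
                    "limit": net.limit,
                    "subnetworks": net.subnetworks,
                    "unplaced": net.unplaced,
                },
                fh, indent=2,
            )
        return ["network_edges.tsv", "network_summary.json"]

    def s_spatial():
        if not aln.coords:
            raise ValueError("no deme coordinates supplied")
        seed = _stage_seed(cfg.seed, "spatial")
        gd = pairwise_differences(aln)
        deme_km = geo_distances(aln.coords)
        ind_geo = np.array(
            [[deme_km.loc[aln.deme_of[i], aln.deme_of[j]] for j in aln.ids]
             for i in aln.ids]
        )
        cor = spatial_autocorrelogram(
            gd, ind_geo, cfg.class_size_km, seed=seed
        )
        cor.to_frame().to_csv(out / "correlogram.tsv", sep="\t", index=False)
        ph = pairwise_phist(aln, n_perm=min(cfg.n_perm, 2000), seed=seed)
        km = deme_km.loc[ph.demes, ph.demes].to_numpy()
        R, p = mantel(ph.phist.to_numpy(), km, n_perm=cfg.n_perm, seed=seed)
        pd.DataFrame([{"mantel_R": R, "p": p,
                       "x_intercept_km": cor.x_intercept}]).to_csv(
            out / "mantel.tsv", sep="\t", index=False)
        return ["correlogram.tsv", "mantel.tsv"]

    def s_mismatch():
        seed = _stage_seed(cfg.seed, "mismatch")
        subsets: dict[str, list[str]] = {
            d: aln.deme_members(d) for d in aln.demes
        }
        if aln.group_of:
            for g in sorted(set(aln.group_of.values())):
                subsets[g] = [
                    i for i in aln.ids
                    if aln.group_of.get(aln.deme_of[i]) == g
                ]
        subsets["All"] = list(aln.ids)
        rows = []
        for k, (name, ids) in enumerate(subsets.items()):
            if len(ids) < 3:
                continue
            obs, mean = observed_mismatch(aln, ids)
            dem = fit_demographic(obs, len(ids), n_boot=cfg.n_boot_mismatch,
                                  seed=seed + k, rate_model=rate_model)
            spa = fit_spatial(obs, len(ids), n_boot=cfg.n_boot_mismatch,
                              seed=seed + k, rate_model=rate_model)
            try:
                fs, fs_p = fu_fs(aln, ids, n_sim=cfg.n_boot_mismatch,
                                 seed=seed + k)
            except ValueError:
                fs, fs_p = np.nan, np.nan
            rows.append({
                "subset": name, "n": len(ids), "obs_mean": round(mean, 3),
                "dem_tau": round(dem.params["tau"], 3),
                "dem_T_years": round(dem.conversions["T_years"], 0),
                "dem_theta0": round(dem.params["theta0"], 3),
                "dem_N0": round(dem.conversions["N0"], 0),
                "dem_theta1": round(dem.params["theta1"], 3),
                "dem_N1": round(dem.conversions["N1"], 0),
                "dem_P_SSD": dem.p_ssd,
                "spa_tau": round(spa.params["tau"], 3),
                "spa_T_years": round(spa.conversions["T_years"], 0),
                "spa_theta": round(spa.params["theta"], 3),
                "spa_N": round(spa.conversions["N"], 0),
                "spa_M": round(spa.params["M"], 3),
                "spa_m": spa.conversions["m_immigration"],
                "spa_P_SSD": spa.p_ssd,
                "fu_FS": round(fs, 3) if np.isfinite(fs) else fs,
                "fu_p": fs_p,
            })
        pd.DataFrame(rows).to_csv(out / "mismatch.tsv", sep="\t", index=False)
        return ["mismatch.tsv"]

    def s_im():
        seed = _stage_seed(cfg.seed, "im")
        rows = []
        for k, (d0, d1) in enumerate(cfg.im_pairs):
            imcfg = IMConfig(
                theta_max=cfg.im_theta_max, M_max=cfg.im_M_max,
                T_max=cfg.im_T_max, steps=cfg.im_steps,
                n_chains=cfg.im_chains, seed=seed + k,
            )
            post = run_mdiv(aln, (d0, d1), imcfg)
            summ = summarize_im(post, rate_model)
            pd.DataFrame({k2: v for k2, v in post.traces.items()}).to_csv(
                out / f"im_trace_{d0}_{d1}.tsv", sep="\t", index=False
            )
            rows.append({
                "pair": f"{d0}-{d1}", "theta": round(summ["theta"], 4),
                "M": round(summ["M"], 4), "T_scaled": round(summ["T_scaled"], 4),
                "TMRCA_mut": round(summ["TMRCA_mut"], 4),
                "N_ef_lo": round(summ["N_ef_range"][0], 0),
                "N_ef_hi": round(summ["N_ef_range"][1], 0),
                "T_lo": round(summ["T_range"][0], 0),
                "T_hi": round(summ["T_range"][1], 0),
                "TMRCA_lo": round(summ["TMRCA_range"][0], 0),
                "TMRCA_hi": round(summ["TMRCA_range"][1], 0),
                "flagged": summ["flagged"],
            })
        pd.DataFrame(rows).to_csv(out / "im_summary.tsv", sep="\t",
                                  index=False)
        return ["im_summary.tsv"]

    stage("diversity", s_diversity)
    stage("structure", s_structure)
    stage("network", s_network)
    if cfg.coords:
        stage("spatial", s_spatial)
    stage("mismatch", s_mismatch)
    if cfg.run_im and cfg.im_pairs:
        stage("im", s_im)

    manifest["runtime_s"] = round(time.time() - t_all, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
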