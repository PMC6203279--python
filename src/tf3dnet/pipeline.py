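"""End-to-end orchestration: simulate -> CCL -> network -> structure ->
occupancy, with a YAML config, per-stage logging and a provenance manifest.

Re-running the same config reproduces every stochastic output
bit-identically: all randomness derives from the config seed, and the
manifest records the config hash, the seed, and a SHA-256 of every file
written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import core_io, hic_ccl, occupancy_stats, structure3d, synthetic, tf_network

__all__ = ["RunConfig", "load_config", "run_pipeline"]

log = logging.getLogger("tf3dnet")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "tf3dnet_out"
    synthetic: dict = field(default_factory=dict)
    ccl: dict = field(default_factory=dict)
    network: dict = field(default_factory=lambda: {"n_perm": 200,
                                                   "fdr": 0.05})
    structure: dict = field(default_factory=lambda: {"threshold_radii": 3.0,
                                                     "n_perm": 100,
                                                     "mode": "all"})
    occupancy: dict = field(default_factory=dict)

    def spec(self) -> synthetic.SyntheticSpec:
        params = dict(self.synthetic)
        tf_specs = tuple(synthetic.TFSpec(**t)
                         for t in params.pop("tf_specs", []))
        planted = tuple(tuple(p) for p in params.pop("planted_pairs", []))
        sspec = synthetic.StructureSpec(**params.pop("structure_spec", {}))
        return synthetic.SyntheticSpec(seed=self.seed, tf_specs=tf_specs,
                                       planted_pairs=planted,
                                       structure_spec=sspec, **params)

    def config_hash(self) -> str:
        # out_dir is deployment detail, not part of the scientific config
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True)
                              .encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = RunConfig(**data)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in dependency order; returns the output dir.

    Stage failures abort with the stage name attached to the exception.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.spec()
    if not spec.tf_specs:
        raise ValueError("config defines no TFs (synthetic.tf_specs)")
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "stages": {}, "files": {}}
    stage = "simulate"
    try:
        t0 = time.time()
        maps, site_sets, annotation = synthetic.make_contact_map(spec)
        structure, struct_sites = synthetic.make_structure(spec)
        occ_data = synthetic.make_occupancy_sites(spec)
        for chrom, cmap in maps.items():
            core_io.write_contact_map(cmap, out / f"contacts_{chrom}.tsv")
        for ss in site_sets:
            core_io.write_sites(ss, out / f"sites_{ss.tf_id}.narrowPeak")
        core_io.write_structure(structure, out / "structure.tsv")
        log.info("simulate: %d TFs, %d chromosomes", len(site_sets),
                 len(maps))
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        stage = "ccl"
        t0 = time.time()
        ccl_cfg = hic_ccl.CCLConfig(**config.ccl)
        tables = {}
        for chrom, cmap in maps.items():
            filtered = hic_ccl.filter_low_coverage(
                cmap, ccl_cfg.low_coverage_fraction)
            profile = hic_ccl.expected_profile(filtered)
            tables[chrom] = hic_ccl.pair_score_table(filtered, profile,
                                                     ccl_cfg)
        rows = []
        for ss in site_sets:
            vec = hic_ccl.ccl_homotypic(ss, ss.bound_sites, tables,
                                        config=ccl_cfg)
            for (_, site), score, np_ in zip(vec.sites.iterrows(), vec.ccl,
                                             vec.n_pairs):
                rows.append((ss.tf_id, site["chrom"], site["start"],
                             site["end"], score, np_))
        with open(out / "ccl_homotypic.tsv", "w") as fh:
            fh.write("tf\tchrom\tstart\tend\tccl\tn_pairs\n")
            for r in rows:
                fh.write("\t".join(map(str, r)) + "\n")
        log.info("ccl: %d homotypic score rows", len(rows))
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        stage = "network"
        t0 = time.time()
        n_perm = int(config.network.get("n_perm", 200))
        fdr = float(config.network.get("fdr", 0.05))
        rng = np.random.default_rng(config.seed)
        directions = {}
        ce = {}
        tf_ids = [ss.tf_id for ss in site_sets]
        for a in tf_ids:
            for b in tf_ids:
                if a == b:
                    continue
                sa = next(ss for ss in site_sets if ss.tf_id == a)
                obs, null = tf_network.heterotypic_null(
                    site_sets, a, b, tables, n_perm,
                    seed=int(rng.integers(2 ** 31)))
                directions[(a, b)] = (obs, null)
                ce[(a, b)] = tf_network.ce_score(obs, null)
        calls = tf_network.call_significant_pairs(directions, fdr=fdr)
        calls.to_csv(out / "pair_calls.tsv", sep="\t", index=False)
        ranked = tf_network.rank_pairs(directions)
        ranked.to_csv(out / "pair_ranking.tsv", sep="\t", index=False)
        if len(tf_ids) >= 3:
            mat = tf_network.PairMatrix(
                tf_ids, np.array([[ce.get((a, b), 0.0) for b in tf_ids]
                                  for a in tf_ids]))
            clus = tf_network.cluster_tfs(mat)
            with open(out / "ce_clusters.tsv", "w") as fh:
                fh.write("tf\tgroup\n")
                for tf, g in clus.labels.items():
                    fh.write(f"{tf}\t{g}\n")
        log.info("network: %d pairs called, %d significant", len(calls),
                 int(calls["significant"].sum()) if len(calls) else 0)
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        stage = "structure"
        t0 = time.time()
        qc = structure3d.qc_structure(structure)
        s_cfg = config.structure
        pe_rows = []
        if len(struct_sites) >= 2:
            pe, p, obs_n, exp_n = structure3d.pe_score(
                struct_sites[0], struct_sites[1], structure, qc,
                all_site_sets=struct_sites,
                n_perm=int(s_cfg.get("n_perm", 100)),
                threshold=float(s_cfg.get("threshold_radii", 3.0)),
                mode=s_cfg.get("mode", "all"), seed=config.seed)
            pe_rows.append((struct_sites[0].tf_id, struct_sites[1].tf_id,
                            pe, p, obs_n, exp_n))
        with open(out / "pe_scores.tsv", "w") as fh:
            fh.write("tf_a\ttf_b\tpe\tp\tobs\texp\n")
            for r in pe_rows:
                fh.write("\t".join(map(str, r)) + "\n")
        log.info("structure: QC coverage %.2f, %d PE rows",
                 qc.coverage_fraction, len(pe_rows))
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        stage = "occupancy"
        t0 = time.time()
        occ_rows = []
        for tf_id, data in occ_data.items():
            put, bnd = data["putative"], data["bound"]
            if len(put) == 0:
                continue
            table = occupancy_stats.occupancy(
                put, bnd, np.zeros(len(put), dtype=int),
                n_resample=int(config.occupancy.get("n_resample", 200)),
                seed=config.seed)
            row = table.table.iloc[0]
            occ_rows.append((tf_id, row["n_putative"], row["n_bound"],
                             row["occupancy"], row["sd_resample"]))
        with open(out / "occupancy.tsv", "w") as fh:
            fh.write("tf\tn_putative\tn_bound\toccupancy\tsd\n")
            for r in occ_rows:
                fh.write("\t".join(map(str, r)) + "\n")
        log.info("occupancy: %d TFs", len(occ_rows))
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
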