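"""End-to-end orchestration: simulate -> matrix -> trees -> conflict -> rates -> eval.

A run is driven by a plain-text YAML config; every stage writes its outputs
into the run directory and records inputs, seeds, and tallies in a JSON
manifest.  Reruns with the same config and seeds are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import conflict, evaluate, mei_io, rates, simulate, trees
from .matrix import write_het_sidecar, write_nexus

DEFAULT_CONFIG = {
    "seed": 1,
    "stages": ["simulate", "matrix", "tree", "conflict", "rates", "eval"],
    "simulate": {
        "newick": (
            "((((blue:200000,sei:200000):100000,(gray:250000,"
            "(fin:200000,humpback:200000):50000):50000):50000,"
            "minke:350000):400000,right:750000);"
        ),
        "ne": 20000.0,
        "samples_per_species": None,
        "n_loci": 2000,
        "genome_length": 50_000_000,
        "stem_generations": 50000.0,
        "coverage": 20.0,
        "missing_rate": 0.0,
    },
    "tree": {"method": "nj", "bootstrap": 100, "outgroup": "right"},
    "conflict": {"collapse": "all", "mc_reps": None},
    "rates": {"generation_time": 24.4, "years_per_generation_scale": 24.4},
    "eval": {"window_bp": 50},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the configured stages; returns the manifest (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = _merge(DEFAULT_CONFIG, config or {})
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)
    manifest: dict = {"seed": seed, "stages": {}, "files": {}}
    stages = cfg["stages"]

    # validate referenced input paths before any stage runs
    if "matrix" in stages and "simulate" not in stages:
        vcf = (cfg.get("matrix") or {}).get("vcf")
        if not vcf or not Path(vcf).exists():
            raise FileNotFoundError(
                f"matrix stage requires an existing input VCF, got {vcf!r}"
            )

    sim_cfg = cfg["simulate"]
    sp_tree = simulate.SimSpeciesTree(
        newick=sim_cfg["newick"],
        ne=sim_cfg["ne"],
        samples_per_species=sim_cfg.get("samples_per_species"),
    )
    config_obj = simulate.SimConfig(
        n_loci=sim_cfg.get("n_loci"),
        insertion_rate=sim_cfg.get("insertion_rate"),
        genome_length=sim_cfg["genome_length"],
        stem_generations=sim_cfg.get("stem_generations", 0.0),
        coverage=sim_cfg.get("coverage", 20.0),
        missing_rate=sim_cfg.get("missing_rate", 0.0),
    )

    truth = None
    calls = None
    if "simulate" in stages:
        truth = simulate.simulate_insertion_matrix(
            sp_tree, config_obj, seed=int(rng.integers(1, 2**31 - 1))
        )
        calls = simulate.apply_detection_noise(
            truth, config_obj, seed=int(rng.integers(1, 2**31 - 1))
        )
        vcf_path = out / "calls.vcf"
        mei_io.write_mei_vcf(calls, vcf_path)
        truth_vcf = out / "truth.vcf"
        mei_io.write_mei_vcf(truth.to_call_set(), truth_vcf)
        with open(out / "species_map.tsv", "w") as fh:
            for ind in truth.individuals:
                fh.write(f"{ind}\t{truth.species_of[ind]}\n")
        manifest["stages"]["simulate"] = {
            "n_loci": int(truth.matrix.n_loci),
            "n_individuals": len(truth.individuals),
            "n_congruent": int(truth.congruent.sum()),
        }

    matrix = None
    if "matrix" in stages:
        if calls is None:
            calls = mei_io.read_mei_vcf(cfg["matrix"]["vcf"])
        calls = mei_io.filter_calls(calls)
        matrix = mei_io.build_matrix(calls)
        write_nexus(matrix, out / "matrix.nex")
        write_het_sidecar(matrix, out / "matrix.het.tsv")
        counts = mei_io.per_sample_counts(calls)
        with open(out / "sample_counts.tsv", "w") as fh:
            fh.write("sample\tn_calls\tn_het\n")
            for c in counts:
                fh.write(f"{c.sample}\t{c.n_calls}\t{c.n_het}\n")
        manifest["stages"]["matrix"] = {
            "n_loci": matrix.n_loci,
            "n_taxa": matrix.n_taxa,
            "total_calls": counts[-1].n_calls,
            "total_het": counts[-1].n_het,
        }

    species_map = (
        {i: truth.species_of[i] for i in truth.individuals} if truth else None
    )

    if "tree" in stages and matrix is not None:
        tcfg = cfg["tree"]
        tree, support = trees.bootstrap(
            matrix,
            n_reps=int(tcfg.get("bootstrap", 100)),
            method=tcfg.get("method", "nj"),
            seed=int(rng.integers(1, 2**31 - 1)),
        )
        trees.write_newick(tree, out / "tree.nwk")
        manifest["stages"]["tree"] = {
            "method": tcfg.get("method", "nj"),
            "min_support": min(support.values()) if support else None,
        }

    species_matrix = None
    if "conflict" in stages and matrix is not None and species_map is not None:
        species_matrix, diag = conflict.collapse_to_species(
            matrix, species_map, rule=cfg["conflict"].get("collapse", "all")
        )
        table = conflict.intersection_counts(species_matrix)
        table.to_tsv(out / "intersections.tsv")
        manifest["stages"]["conflict"] = {
            "n_counted": table.n_counted,
            "n_skipped_missing": table.n_skipped_missing,
            "n_skipped_empty": table.n_skipped_empty,
            "mixed_loci_per_species": diag.mixed_loci_per_species,
        }

    if "rates" in stages and species_matrix is not None:
        g = float(cfg["rates"].get("generation_time", 24.4))
        # species tree branch lengths are in generations; convert to years
        scale = float(cfg["rates"].get("years_per_generation_scale", g))
        yr_newick = _scale_newick(sim_cfg["newick"], scale)
        stem = sim_cfg.get("stem_generations") or None
        dated = rates.DatedTree.from_newick(
            yr_newick, root_stem_years=scale * stem if stem else None
        )
        assignment = rates.assign_branches(species_matrix, dated)
        tab = rates.branch_rates(
            assignment,
            dated,
            locus_any_het=rates.locus_het_from_matrix(matrix),
            params=rates.RateParams(generation_time_years=g),
        )
        tab.to_csv(out / "rates.tsv", sep="\t", index=False)
        manifest["stages"]["rates"] = {
            "n_assigned": len(assignment.edge_of_locus),
            "n_congruent": assignment.n_congruent,
        }

    if "eval" in stages and truth is not None and calls is not None:
        metrics = evaluate.evaluate_call_set(
            truth.to_call_set(), calls, window_bp=int(cfg["eval"].get("window_bp", 50))
        )
        manifest["stages"]["eval"] = {
            "detr": metrics.detr,
            "tpr": metrics.tpr,
            "genotype_sensitivity": metrics.genotype_sensitivity,
            "genotype_concordance": metrics.genotype_concordance,
        }

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _scale_newick(newick: str, factor: float) -> str:
    """Multiply all branch lengths of a newick string by *factor*."""
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick")
    for e in t.preorder_edge_iter():
        if e.length is not None:
            e.length = e.length * factor
    return t.as_string(schema="newick", suppress_rooting=True)
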