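"""End-to-end orchestration: simulate -> mfa -> spatial -> decompose -> enrich
-> constellation, driven by a single validated config with a run manifest.

The pipeline is deliberately file-based: every stage reads the files the
previous stage wrote, so each stage is also independently runnable from the
CLI.  A manifest (JSON) records inputs, every parameter with its
default-vs-explicit provenance, seeds, and sha256 checksums of all outputs;
identical configs give bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import comparative, decomposition as decompose, enrichment, io, mfa, \
    simulate, spatial
from .errors import ConfigError, DosagescopeError, InputError

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("simulate", "mfa", "spatial", "decompose", "enrich", "constellation")

_STAGE_KEYS = {
    "simulate": {f.name for f in fields(simulate.SimulationConfig)},
    "mfa": {"window", "step"},
    "spatial": {"window_genes", "compare", "quantile", "correct_frequency_bias",
                "alpha"},
    "decompose": {"thresholds"},
    "enrich": {"n_random"},
    "constellation": {"step"},
}


class RunConfig:
    """Validated pipeline configuration.

    Top-level keys: ``stages`` (subset of the known stages, dependency
    order enforced), ``seed`` (mandatory when any stochastic stage runs),
    ``outdir``, and one optional mapping per stage.  Unknown keys anywhere
    are rejected.
    """

    def __init__(self, raw: dict):
        raw = dict(raw)
        known_top = {"stages", "seed", "outdir"} | set(STAGES)
        unknown = set(raw) - known_top
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        self.stages: List[str] = list(raw.get("stages", STAGES))
        for s in self.stages:
            if s not in STAGES:
                raise ConfigError(f"unknown stage {s!r}")
        self.outdir = Path(raw.get("outdir", "dosagescope_out"))
        self.seed = raw.get("seed")
        stochastic = {"simulate", "enrich"} & set(self.stages)
        if stochastic and self.seed is None:
            raise ConfigError(
                f"stages {sorted(stochastic)} are stochastic: config needs a seed")
        self.params: Dict[str, dict] = {}
        self.explicit: Dict[str, set] = {}
        for stage in STAGES:
            given = raw.get(stage, {}) or {}
            if not isinstance(given, dict):
                raise ConfigError(f"{stage}: expected a mapping of parameters")
            unknown = set(given) - _STAGE_KEYS[stage]
            if unknown:
                raise ConfigError(f"{stage}: unknown parameters {sorted(unknown)}")
            self.params[stage] = given
            self.explicit[stage] = set(given)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_curve_tsv(curve: spatial.WindowCurve, path: Path, value_name: str):
    locs, vals = curve.kept()
    pd.DataFrame({"location": locs, value_name: vals}).to_csv(
        path, sep="\t", index=False)


def run_pipeline(config: dict, outdir: Optional[Path] = None) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest (also written to ``<outdir>/manifest.json``).
    A failure in one stage halts all dependent stages with an error naming
    the stage.
    """
    cfg = RunConfig(config)
    outdir = Path(outdir) if outdir is not None else cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"stages": [], "parameters": {}, "seed": cfg.seed,
                      "outputs": {}}
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        params = cfg.params[stage]
        manifest["parameters"][stage] = {
            k: {"value": v, "provenance": "explicit"} for k, v in params.items()}
        try:
            produced = _STAGE_RUNNERS[stage](cfg, outdir, manifest)
        except DosagescopeError:
            raise
        except FileNotFoundError as exc:
            raise InputError(
                f"stage {stage!r}: missing dependency output ({exc})") from exc
        manifest["stages"].append(stage)
        for p in produced:
            manifest["outputs"][p.name] = _sha256(p)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    return manifest


# ---------------------------------------------------------------------------
# stage runners (each returns the list of files it wrote)
# ---------------------------------------------------------------------------

def _run_simulate(cfg: RunConfig, outdir: Path, manifest: dict) -> List[Path]:
    params = dict(cfg.params["simulate"])
    params.setdefault("seed", cfg.seed)
    if "inversion" in params and params["inversion"] is not None:
        params["inversion"] = tuple(params["inversion"])
    if "categories" in params:
        params["categories"] = tuple(params["categories"])
    sim_cfg = simulate.SimulationConfig(**params)
    for k, v in asdict(sim_cfg).items():
        manifest["parameters"]["simulate"].setdefault(
            k, {"value": v, "provenance": "default"})
    ds = simulate.simulate_dataset(sim_cfg)

    rng = np.random.default_rng(sim_cfg.seed + 1)
    chrom_b, genes_b, orth, orth_truth = simulate.simulate_ortholog_pair(
        sim_cfg, ds.chrom, ds.genes, rng)

    paths = []
    p = outdir / "genome.gff3"
    io.write_gff3(ds.chrom, ds.genes, p)
    paths.append(p)
    p = outdir / "genome_b.gff3"
    io.write_gff3(chrom_b, genes_b, p)
    paths.append(p)
    for name, track in (("coverage_exp.bedgraph", ds.coverage_exp),
                        ("coverage_stat.bedgraph", ds.coverage_stat)):
        p = outdir / name
        io.write_coverage(track, p)
        paths.append(p)
    p = outdir / "counts.tsv"
    io.write_counts(ds.counts, p)
    paths.append(p)
    p = outdir / "orthologs.proteinortho.tsv"
    io.write_proteinortho(orth, p)
    paths.append(p)
    p = outdir / "categories.tsv"
    with open(p, "w") as fh:
        fh.write("gene_id\tcategory\n")
        for g in ds.genes:
            fh.write(f"{g.gene_id}\t{g.category}\n")
    paths.append(p)
    p = outdir / "truth.json"
    truth = {
        "gradient_ratio": sim_cfg.gradient_ratio,
        "oriC": ds.chrom.oriC, "ter": ds.chrom.ter,
        "breakpoints": ds.breakpoints,
        "oriC_offset": int(orth_truth["oriC_offset"]),
        "per_gene": ds.truth.reset_index().to_dict(orient="list"),
    }
    p.write_text(json.dumps(truth, indent=2, default=str))
    paths.append(p)
    return paths


def _run_mfa(cfg: RunConfig, outdir: Path, manifest: dict) -> List[Path]:
    params = cfg.params["mfa"]
    window = params.get("window", 5000)
    step = params.get("step", window // 5)
    manifest["parameters"]["mfa"] = {
        "window": {"value": window,
                   "provenance": "explicit" if "window" in cfg.explicit["mfa"]
                   else "default"},
        "step": {"value": step,
                 "provenance": "explicit" if "step" in cfg.explicit["mfa"]
                 else "default"},
    }
    cov_exp = io.read_coverage(outdir / "coverage_exp.bedgraph")
    cov_stat = io.read_coverage(outdir / "coverage_stat.bedgraph")
    chrom, _, _ = io.read_gff3(outdir / "genome.gff3")
    profile = mfa.compute_mfa_profile(cov_exp, cov_stat, window, step)
    model = mfa.fit_copy_number_model(profile, chrom)

    p1 = outdir / "mfa_profile.tsv"
    pd.DataFrame({"midpoint": profile.midpoints,
                  "log2_ratio": profile.log2_ratio}).to_csv(p1, sep="\t",
                                                            index=False)
    p2 = outdir / "copy_model.json"
    p2.write_text(json.dumps(model.to_dict(), indent=2))
    return [p1, p2]


def _run_spatial(cfg: RunConfig, outdir: Path, manifest: dict) -> List[Path]:
    params = cfg.params["spatial"]
    window = params.get("window_genes", 300)
    cond_a, cond_b = params.get("compare", ("EXP", "STAT"))
    quantile = params.get("quantile", True)
    correct = params.get("correct_frequency_bias", True)

    counts = io.read_counts(outdir / "counts.tsv")
    chrom, genes, _ = io.read_gff3(outdir / "genome.gff3")
    model = mfa.CopyNumberModel.from_dict(
        json.loads((outdir / "copy_model.json").read_text()))

    expr = spatial.normalize_expression(counts, quantile=quantile)
    fold = spatial.gene_fold_changes(expr, cond_a, cond_b)
    bias = spatial.updown_bias_curve(fold, genes, chrom, window)
    fc_curve = spatial.fold_change_curve(fold, genes, chrom, window)

    c = 1.0
    if correct:
        flat = mfa.CopyNumberModel(model.length, model.oriC_est, model.ter_est,
                                   0.0, 0.0, (0.0, 0.0), (0.0, 0.0), flat=True)
        zero = mfa.zero_difference_locus(model, flat)
        fc_curve, c = spatial.frequency_bias_correct(fc_curve, fold, genes,
                                                     chrom, zero)

    p1 = outdir / "updown_bias.tsv"
    _write_curve_tsv(bias, p1, "bias")
    p2 = outdir / "fold_change_curve.tsv"
    _write_curve_tsv(fc_curve, p2, "mean_fold_change")
    p3 = outdir / "gene_fold_changes.tsv"
    out = (fold.f_total / c).rename("f_total").to_frame()
    out.index.name = "gene_id"
    out.to_csv(p3, sep="\t")
    return [p1, p2, p3]


def _run_decompose(cfg: RunConfig, outdir: Path, manifest: dict) -> List[Path]:
    thresholds = cfg.params["decompose"].get("thresholds",
                                             decompose.DEFAULT_STRINGENCY)
    fold = pd.read_csv(outdir / "gene_fold_changes.tsv", sep="\t",
                       comment="#").set_index("gene_id")["f_total"]
    chrom, genes, _ = io.read_gff3(outdir / "genome.gff3")
    model = mfa.CopyNumberModel.from_dict(
        json.loads((outdir / "copy_model.json").read_text()))
    mids = pd.Series({g.gene_id: g.midpoint for g in genes})
    f_copy = pd.Series(2.0 ** np.asarray(
        model.log2_copy_at(mids.to_numpy())), index=mids.index)
    table = decompose.decompose_table(fold, f_copy)
    subsets = decompose.stringency_subsets(table, thresholds)

    p1 = outdir / "decomposition.tsv"
    table.index.name = "gene_id"
    table.to_csv(p1, sep="\t")
    p2 = outdir / "subsets.json"
    p2.write_text(json.dumps(
        {kind: [sorted(s) for s in sets] for kind, sets in subsets.items()},
        indent=2))
    return [p1, p2]


def _run_enrich(cfg: RunConfig, outdir: Path, manifest: dict) -> List[Path]:
    n_random = cfg.params["enrich"].get("n_random", 1000)
    table = pd.read_csv(outdir / "decomposition.tsv", sep="\t",
                        comment="#").set_index("gene_id")
    chrom, genes, _ = io.read_gff3(outdir / "genome.gff3")
    categories = io.read_categories(outdir / "categories.tsv")
    genes = io.merge_categories(genes, categories)
    query = set(table.index[table["dominance"] == "copy"])
    results = enrichment.functional_zscores(query, genes, n_random=n_random,
                                            seed=cfg.seed + 2)
    p = outdir / "enrichment.tsv"
    pd.DataFrame([asdict(r) for r in results]).to_csv(p, sep="\t", index=False)
    return [p]


def _run_constellation(cfg: RunConfig, outdir: Path, manifest: dict) -> List[Path]:
    step = cfg.params["constellation"].get("step")
    chrom_a, genes_a, _ = io.read_gff3(outdir / "genome.gff3")
    chrom_b, genes_b, _ = io.read_gff3(outdir / "genome_b.gff3")
    orth = io.read_proteinortho(outdir / "orthologs.proteinortho.tsv")
    res = comparative.constellation_scan(
        orth, comparative.SpeciesGeometry.from_genes(chrom_a, genes_a),
        comparative.SpeciesGeometry.from_genes(chrom_b, genes_b), step=step)
    p1 = outdir / "constellation_matrix.tsv"
    pd.DataFrame(res.matrix, index=res.candidates_a,
                 columns=res.candidates_b).to_csv(p1, sep="\t")
    p2 = outdir / "constellation.json"
    p2.write_text(json.dumps({
        "best_a": res.best_a, "best_b": res.best_b, "r_max": res.r_max,
        "n_orthologs": res.n_orthologs, "ridge_score": res.ridge_score,
        "degenerate": res.degenerate}, indent=2))
    return [p1, p2]


_STAGE_RUNNERS = {
    "simulate": _run_simulate,
    "mfa": _run_mfa,
    "spatial": _run_spatial,
    "decompose": _run_decompose,
    "enrich": _run_enrich,
    "constellation": _run_constellation,
}
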