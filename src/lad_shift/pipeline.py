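"""Manifest-driven end-to-end pipeline.

Ties the stages together: digest -> count -> normalize -> segment ->
call-lads -> call-drs -> compare-lads -> integrate. A JSON manifest names
the inputs (genome FASTA, per-condition read-pair BEDs, gene annotation,
expression matrices, optional reference fold-change table) and the
parameter block; one top-level seed feeds named per-stage substreams.
Every output file carries the manifest hash so a run directory is
self-describing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential_regions as dr
from . import expression_integration as ei
from . import lad_comparison as lc
from .fragment_map import count_reads, digest_genome, read_bed, write_bed
from .normalization import log2_ratio, quantile_normalize, smooth, write_bedgraph
from .segmentation import call_lads, cbs_segment, segments_to_frame
from .synthetic_data import read_fasta

logger = logging.getLogger(__name__)

MANIFEST_VERSION = 1

DEFAULT_PARAMS: dict = {
    "pseudocount": None,      # None -> 0.5 / min(library size)
    "half_window": 50,        # smoothing half window, fragments
    "alpha": 0.01,            # CBS split significance
    "n_perm": 1000,           # CBS permutations
    "merge_gap": 5000,        # bp; LAD/DR merge distance
    "min_size": 15000,        # bp; minimum LAD/DR size
    "ratio_factor": 2.0,      # composite filter rule (b)
    "window": 100000,         # bp; gene-centered DamID window
    "fdr": 0.05,              # DE false discovery rate
    "lfc": 0.5,               # DE |log2FC| threshold
    "enrichment_iterations": 100,
}

_PARAM_RANGES = {
    "half_window": (0, 10_000),
    "alpha": (0.0, 1.0),
    "n_perm": (1, 1_000_000),
    "merge_gap": (0, 10_000_000),
    "min_size": (0, 100_000_000),
    "ratio_factor": (1.0, 1000.0),
    "window": (1, 100_000_000),
    "fdr": (0.0, 1.0),
    "lfc": (0.0, 100.0),
    "enrichment_iterations": (1, 1_000_000),
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    genome: str
    read_pairs: dict[str, dict[str, str]]  # condition -> {"lamin": path, "dam": path}
    control: str
    genes: str | None = None
    expression: dict[str, str] = field(default_factory=dict)  # condition -> TSV path
    reference: str | None = None
    params: dict = field(default_factory=dict)
    seed: int = 0
    version: int = MANIFEST_VERSION

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            data = json.load(fh)
        data.setdefault("version", MANIFEST_VERSION)
        return cls(**data)

    def merged_params(self) -> dict:
        p = dict(DEFAULT_PARAMS)
        p.update(self.params)
        return p

    def hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_manifest(manifest: RunManifest) -> list[str]:
    """Every violated invariant, not only the first."""
    errors: list[str] = []
    paths = [("genome", manifest.genome)]
    for cond, pair in manifest.read_pairs.items():
        for role in ("lamin", "dam"):
            if role not in pair:
                errors.append(f"condition {cond!r} missing {role!r} read file")
            else:
                paths.append((f"{cond}/{role}", pair[role]))
    if manifest.genes:
        paths.append(("genes", manifest.genes))
    for cond, p in manifest.expression.items():
        paths.append((f"expression/{cond}", p))
    if manifest.reference:
        paths.append(("reference", manifest.reference))
    for label, p in paths:
        if not Path(p).exists():
            errors.append(f"{label}: path does not exist: {p}")
    if manifest.control not in manifest.read_pairs:
        errors.append(f"control condition {manifest.control!r} has no read pair")
    params = manifest.merged_params()
    for key, (lo, hi) in _PARAM_RANGES.items():
        v = params.get(key)
        if v is None:
            continue
        if not (lo <= v <= hi):
            errors.append(f"{key} out of range [{lo}, {hi}]: {v}")
    unknown = set(manifest.params) - set(DEFAULT_PARAMS)
    if unknown:
        errors.append(f"unknown parameters: {sorted(unknown)}")
    return errors


def _write_tsv(df: pd.DataFrame, path: Path, mhash: str, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# manifest={mhash}\n")
        df.to_csv(fh, sep="\t", index=index)


def load_genes(path) -> pd.DataFrame:
    """Gene table from BED4+ (name column = gene ID) or GFF3 (gene features)."""
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                gid = attrs.get("ID") or attrs.get("gene_id") or f"{f[0]}:{f[3]}"
                rows.append((gid, f[0], int(f[3]) - 1, int(f[4]), f[6]))
        df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    else:
        bed = read_bed(path)
        if "name" not in bed.columns:
            raise ValueError("gene BED needs a 4th (name) column with gene IDs")
        df = bed.rename(columns={"name": "gene_id"})
        if "strand" not in df.columns:
            df["strand"] = "."
        df = df[["gene_id", "chrom", "start", "end", "strand"]]
    return df.set_index("gene_id")


def run_pipeline(manifest: RunManifest, outdir) -> Path:
    """Execute the full analysis; returns the run directory."""
    errors = validate_manifest(manifest)
    if errors:
        raise PipelineError("validate", "; ".join(errors))
    params = manifest.merged_params()
    logger.info("run_pipeline parameters: %s", json.dumps(params))
    mhash = manifest.hash()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_info.json").write_text(json.dumps(
        {"manifest_hash": mhash, "params": params, "seed": manifest.seed}, indent=2))

    def stage(name):
        logger.info("stage: %s", name)
        return name

    try:
        stage("digest")
        genome = read_fasta(manifest.genome)
        fmap = digest_genome(genome)
        write_bed(fmap.to_bed(), out / "fragments.bed")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("digest", str(exc)) from exc

    conditions = list(manifest.read_pairs)
    tracks = {}
    try:
        stage("count+normalize")
        raw = {}
        for cond in conditions:
            lam = count_reads(fmap, read_bed(manifest.read_pairs[cond]["lamin"]), f"{cond}/lamin")
            dam = count_reads(fmap, read_bed(manifest.read_pairs[cond]["dam"]), f"{cond}/dam")
            raw[cond] = log2_ratio(lam, dam, params["pseudocount"], condition=cond)
        normed = quantile_normalize(list(raw.values())) if len(raw) > 1 else list(raw.values())
        for cond, tr in zip(conditions, normed):
            tracks[cond] = tr
            # smoothed profile tracks are for display; segmentation and window
            # statistics run on the unsmoothed normalized values
            write_bedgraph(smooth(tr, params["half_window"]),
                           out / f"profile_{cond}.bedgraph")
    except Exception as exc:
        raise PipelineError("normalize", str(exc)) from exc

    segments, lads = {}, {}
    try:
        stage("segment+call-lads")
        for ci, cond in enumerate(conditions):
            segs = cbs_segment(tracks[cond], alpha=params["alpha"], n_perm=params["n_perm"],
                               seed=[manifest.seed, 10, ci])
            segments[cond] = segs
            _write_tsv(segments_to_frame(segs), out / f"segments_{cond}.tsv", mhash)
            lads[cond] = call_lads(segs, params["merge_gap"], params["min_size"], condition=cond)
            write_bed(lads[cond], out / f"lads_{cond}.bed", columns=["chrom", "start", "end"])
    except Exception as exc:
        raise PipelineError("segment", str(exc)) from exc

    control = manifest.control
    nets = [c for c in conditions if c != control]
    drs_by_net = {}
    try:
        stage("call-drs")
        enr_rows = []
        for ni, net in enumerate(nets):
            windows = dr.union_windows(segments[control], segments[net])
            mc = dr.window_means(windows, tracks[control])
            mn = dr.window_means(windows, tracks[net])
            drs_by_net[net] = dr.call_drs(windows, mc, mn, lads[control], lads[net],
                                          params["ratio_factor"], params["merge_gap"],
                                          params["min_size"])
            df = drs_by_net[net].copy()
            df["name"] = df["dr_class"]
            write_bed(df, out / f"drs_{net}.bed", columns=["chrom", "start", "end", "name"])
            enr = dr.fisher_enrichment(windows, tracks[control], tracks[net],
                                       params["ratio_factor"],
                                       n_iter=params["enrichment_iterations"],
                                       seed=[manifest.seed, 20, ni])
            enr_rows.append({"net": net, "observed": enr.observed_highlighted,
                             "null_mean": enr.null_mean_highlighted,
                             "odds_ratio": enr.odds_ratio, "p": enr.p_value})
        if enr_rows:
            from statsmodels.stats.multitest import multipletests
            enr_df = pd.DataFrame(enr_rows)
            enr_df["adj_p"] = multipletests(enr_df["p"], method="fdr_bh")[1]
            _write_tsv(enr_df, out / "dr_enrichment.tsv", mhash)
    except Exception as exc:
        raise PipelineError("call-drs", str(exc)) from exc

    genes = load_genes(manifest.genes) if manifest.genes else None
    try:
        stage("compare-lads")
        clusters = lc.cluster_lads(lads)
        _write_tsv(lc.intersection_counts(clusters), out / "lad_cluster_signatures.tsv", mhash)
        genome_size = sum(fmap.chrom_lengths.values())
        sets = {f"LADs {c}": lads[c] for c in conditions}
        sets.update({f"DRs {n} {cls}": drs_by_net[n][drs_by_net[n]["dr_class"] == cls]
                     for n in nets for cls in ("IP", "PI")})
        _write_tsv(lc.summary_table(sets, genes, genome_size), out / "summary.tsv", mhash)
    except Exception as exc:
        raise PipelineError("compare-lads", str(exc)) from exc

    try:
        stage("integrate")
        if genes is not None and manifest.expression and control in manifest.expression:
            expr = {c: pd.read_csv(p, sep="\t", index_col=0, comment="#")
                    for c, p in manifest.expression.items()}
            reference = None
            if manifest.reference:
                reference = pd.read_csv(manifest.reference, sep="\t", index_col=0,
                                        comment="#").iloc[:, 0]
            conc_rows = []
            for net in nets:
                if net not in expr:
                    continue
                gt = genes.copy()
                de = ei.call_de(expr[net], expr[control], params["fdr"], params["lfc"])
                gt = gt.join(de[["log2fc", "adj_p", "de_call"]])
                gt["position_class"] = ei.classify_position(gt, lads[control], lads[net],
                                                            drs_by_net[net])
                gt["damid_delta"] = ei.gene_window_delta(gt, tracks[control], tracks[net],
                                                         params["window"])
                _write_tsv(gt, out / f"gene_table_{net}.tsv", mhash, index=True)
                conc = ei.concordance(gt)
                row = {"net": net, "n": conc.n_genes,
                       "expected_direction_fraction": conc.expected_direction_fraction,
                       "fisher_odds_ratio": conc.odds_ratio, "fisher_p": conc.fisher_p}
                if reference is not None:
                    ro = ei.reference_overlap(gt, reference)
                    row.update({"ks_up_D": ro.ks_up[0] if ro.ks_up else np.nan,
                                "ks_up_p": ro.ks_up[1] if ro.ks_up else np.nan,
                                "ks_down_D": ro.ks_down[0] if ro.ks_down else np.nan,
                                "ks_down_p": ro.ks_down[1] if ro.ks_down else np.nan,
                                "net_up_in_ref_up": ro.net_up_in_ref_up,
                                "net_down_in_ref_up": ro.net_down_in_ref_up})
                conc_rows.append(row)
            if conc_rows:
                _write_tsv(pd.DataFrame(conc_rows), out / "concordance.tsv", mhash)
    except Exception as exc:
        raise PipelineError("integrate", str(exc)) from exc

    return out
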