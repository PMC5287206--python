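"""Synthetic DamID study generator.

Emulates the data layout of a lamin-B1 DamID comparison between a control
cell line and lines overexpressing tissue-specific nuclear envelope
transmembrane proteins (NETs): a small multi-chromosome genome with GATC
motifs at realistic density, per-condition paired Dam-LaminB1 / Dam-alone
read sets with planted LAD structure, condition-specific LAD gains (IP)
and losses (PI), replicate log2-intensity expression matrices whose
differential genes are coupled to the planted positional shifts at a
configurable concordance rate, and a reference-differentiation fold-change
table with a configurable overlap with the NET-regulated genes.

Planted structure per condition
-------------------------------
* constitutive LADs: long, shared by every condition;
* shared facultative LADs: shorter, also in every condition;
* PI regions (one NET each): LADs everywhere *except* their NET;
* IP regions (one NET each): LADs *only* in their NET.

With the defaults the planted LADs cover roughly a third of the genome in
every condition, which both mirrors the LAD coverage of mammalian genomes
and keeps library-size-normalized log2 ratios centred on the planted
per-fragment means.

All randomness flows from ``SimulationConfig.seed`` through named
substreams, so any stage can be regenerated independently and a fixed seed
fixes every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragment_map import FragmentMap, digest_genome
from .intervals import overlaps_any

_BASES = b"ACGT"
_MOTIF = b"GATC"

# substream tags
_S_GENOME, _S_TRUTH, _S_READS, _S_EXPR, _S_REF = 0, 1, 2, 3, 4


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study. Lengths in bp, signals in log2 units."""

    seed: int = 0
    n_chromosomes: int = 5
    chrom_length_bp: int = 2_000_000
    gatc_rate: float = 1.0 / 256.0  # expected GATC density per bp
    n_constitutive_lads: int = 3
    constitutive_lad_len_bp: tuple[int, int] = (400_000, 600_000)
    n_facultative_lads: int = 6  # shared facultative LADs
    facultative_lad_len_bp: tuple[int, int] = (30_000, 80_000)
    n_drs_per_class: int = 20  # planted IP and PI regions per NET condition
    dr_len_bp: tuple[int, int] = (18_000, 35_000)
    lad_log2_mean: float = 1.0
    nonlad_log2_mean: float = -1.0
    noise_sd: float = 0.5  # per-fragment sd of the planted log2 ratio
    reads_per_sample: int = 500_000
    dispersion: float = 0.05  # negative-binomial overdispersion (0 -> Poisson)
    read_length_bp: int = 75
    n_genes: int = 1000
    gene_len_bp: tuple[int, int] = (2_000, 15_000)
    n_de_genes: int = 200
    de_log2fc_mean: float = 1.5
    de_repositioned_fraction: float = 0.5  # fraction of DE genes drawn from DR-overlapping genes
    expr_noise_sd: float = 0.3  # replicate sd of log2 intensities
    n_replicates: int = 3
    concordance_rate: float = 0.7  # P(expected direction) for repositioned DE genes
    ref_overlap_rate: float = 0.3  # fraction of reference DE genes shared with the NET DE set
    control_label: str = "WT"
    net_conditions: tuple[str, ...] = ("NET29", "NET39", "NET47")
    min_feature_gap_bp: int = 20_000

    def validate(self) -> None:
        if self.chrom_length_bp <= 0 or self.n_chromosomes <= 0:
            raise ValueError("genome dimensions must be positive")
        if not (0.0 <= self.concordance_rate <= 1.0):
            raise ValueError("concordance_rate must lie in [0, 1]")
        if self.noise_sd < 0 or self.expr_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes cannot exceed n_genes")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for rng_pair in (self.constitutive_lad_len_bp, self.facultative_lad_len_bp,
                         self.dr_len_bp, self.gene_len_bp):
            if rng_pair[0] <= 0 or rng_pair[1] < rng_pair[0]:
                raise ValueError(f"invalid length range {rng_pair}")

    @property
    def conditions(self) -> tuple[str, ...]:
        return (self.control_label,) + tuple(self.net_conditions)

    def chrom_lengths(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length_bp for i in range(self.n_chromosomes)}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *stream])


@dataclass
class GroundTruth:
    """Planted structure the pipeline is asked to recover."""

    lads_by_condition: dict[str, pd.DataFrame]
    drs: dict[str, pd.DataFrame]  # NET condition -> chrom/start/end/dr_class
    genes: pd.DataFrame  # gene_id index; chrom/start/end/strand
    de_tables: dict[str, pd.DataFrame]  # NET -> direction/true_lfc/position_class/concordant
    config: SimulationConfig


# --------------------------------------------------------------- genome

def _random_fill(n: int, rng: np.random.Generator) -> bytearray:
    """Random sequence of length n containing no GATC occurrence."""
    if n <= 0:
        return bytearray()
    arr = np.frombuffer(_BASES, dtype=np.uint8)[rng.integers(0, 4, n)]
    ba = bytearray(arr.tobytes())
    i = ba.find(_MOTIF)
    while i != -1:
        ba[i + 3] = _BASES[rng.integers(0, 3)]  # A, C or G; re-scan same spot
        if ba[i + 3] == ord("C"):
            ba[i + 3] = ord("T")
        i = ba.find(_MOTIF, max(i - 3, 0))
    return ba


def simulate_genome(config: SimulationConfig) -> tuple[dict[str, str], FragmentMap]:
    """Random genome with GATC motifs at exponential spacing.

    Motif spacing is exponential with mean 1/gatc_rate (clamped so motifs
    never overlap); the returned FragmentMap is literally the digestion of
    the returned sequences, so the round trip is exact by construction.
    """
    config.validate()
    if config.gatc_rate <= 0:
        raise ValueError("gatc_rate must be positive: zero GATC insertions requested")
    rng = config.rng(_S_GENOME)
    mean_gap = max(1.0 / config.gatc_rate - len(_MOTIF), 1.0)
    sequences: dict[str, str] = {}
    for chrom, length in config.chrom_lengths().items():
        parts = bytearray()
        n_sites = 0
        while len(parts) < length:
            gap = int(rng.exponential(mean_gap))
            parts += _random_fill(gap, rng)
            if len(parts) + len(_MOTIF) <= length:
                parts += _MOTIF
                n_sites += 1
        seq = bytes(parts[:length])
        if n_sites < 2:
            raise ValueError(f"chromosome {chrom} too short to contain >=2 GATC sites "
                             f"at rate {config.gatc_rate:g}")
        sequences[chrom] = seq.decode("ascii")
    return sequences, digest_genome(sequences)


# --------------------------------------------------------------- truth

def _draw_lengths(rng, n, lo_hi) -> np.ndarray:
    lo, hi = lo_hi
    return rng.integers(lo, hi + 1, n)


def _place_features(lengths: np.ndarray, chrom_lengths: dict[str, int],
                    min_gap: int, rng: np.random.Generator,
                    max_tries: int = 50) -> pd.DataFrame:
    """Lay features non-overlappingly along the genome with >=min_gap spacing
    and random exponential slack, in a random order for spatial mixing."""
    n = len(lengths)
    chroms = list(chrom_lengths)
    total = sum(chrom_lengths.values())
    need = int(lengths.sum()) + min_gap * (n + len(chroms))
    if need > total:
        raise ValueError("features (plus spacing) do not fit in the genome")
    slack_mean = (total - need) / max(n + len(chroms), 1)
    for _try in range(max_tries):
        order = rng.permutation(n)
        rows: list[tuple[str, int, int, int]] = []
        ci = 0
        pos = min_gap + int(rng.exponential(slack_mean))
        ok = True
        for fi in order:
            ln = int(lengths[fi])
            while ci < len(chroms) and pos + ln > chrom_lengths[chroms[ci]]:
                ci += 1
                pos = min_gap + int(rng.exponential(slack_mean))
            if ci >= len(chroms):
                ok = False
                break
            rows.append((chroms[ci], pos, pos + ln, int(fi)))
            pos += ln + min_gap + int(rng.exponential(slack_mean))
        if ok:
            df = pd.DataFrame(rows, columns=["chrom", "start", "end", "feature"])
            return df.set_index("feature").sort_index()
    raise RuntimeError("could not place features after retries; genome too crowded")


def simulate_truth(config: SimulationConfig) -> GroundTruth:
    """Plant LADs, DRs, genes and coupled expression changes."""
    config.validate()
    rng = config.rng(_S_TRUTH)
    nets = list(config.net_conditions)
    chrom_lengths = config.chrom_lengths()

    n_const = config.n_constitutive_lads
    n_fac = config.n_facultative_lads
    n_dr = config.n_drs_per_class
    lengths = np.concatenate([
        _draw_lengths(rng, n_const, config.constitutive_lad_len_bp),
        _draw_lengths(rng, n_fac, config.facultative_lad_len_bp),
        _draw_lengths(rng, n_dr * len(nets), config.dr_len_bp),  # PI (LAD lost in its NET)
        _draw_lengths(rng, n_dr * len(nets), config.dr_len_bp),  # IP (LAD gained in its NET)
    ])
    placed = _place_features(lengths, chrom_lengths, config.min_feature_gap_bp, rng)
    coords = placed[["chrom", "start", "end"]]
    i0 = 0
    const = coords.iloc[i0:i0 + n_const]; i0 += n_const
    fac = coords.iloc[i0:i0 + n_fac]; i0 += n_fac
    pi_feats = {net: coords.iloc[i0 + k * n_dr: i0 + (k + 1) * n_dr] for k, net in enumerate(nets)}
    i0 += n_dr * len(nets)
    ip_feats = {net: coords.iloc[i0 + k * n_dr: i0 + (k + 1) * n_dr] for k, net in enumerate(nets)}

    shared = pd.concat([const, fac], ignore_index=True)
    all_pi = pd.concat(list(pi_feats.values()), ignore_index=True) if nets else shared.iloc[0:0]
    lads: dict[str, pd.DataFrame] = {
        config.control_label: pd.concat([shared, all_pi], ignore_index=True)
        .sort_values(["chrom", "start"]).reset_index(drop=True)
    }
    drs: dict[str, pd.DataFrame] = {}
    for net in nets:
        others_pi = [pi_feats[m] for m in nets if m != net]
        lad_n = pd.concat([shared] + others_pi + [ip_feats[net]], ignore_index=True)
        lads[net] = lad_n.sort_values(["chrom", "start"]).reset_index(drop=True)
        dr_ip = ip_feats[net].copy(); dr_ip["dr_class"] = "IP"
        dr_pi = pi_feats[net].copy(); dr_pi["dr_class"] = "PI"
        drs[net] = pd.concat([dr_ip, dr_pi], ignore_index=True) \
            .sort_values(["chrom", "start"]).reset_index(drop=True)

    # genes: uniform placement, overlaps allowed
    glen = _draw_lengths(rng, config.n_genes, config.gene_len_bp)
    chrom_names = list(chrom_lengths)
    gchrom_idx = rng.integers(0, len(chrom_names), config.n_genes)
    gstart = np.array([rng.integers(0, chrom_lengths[chrom_names[c]] - glen[i])
                       for i, c in enumerate(gchrom_idx)])
    genes = pd.DataFrame({
        "chrom": [chrom_names[c] for c in gchrom_idx],
        "start": gstart,
        "end": gstart + glen,
        "strand": rng.choice(["+", "-"], config.n_genes),
    }, index=pd.Index([f"G{i:05d}" for i in range(config.n_genes)], name="gene_id"))
    genes = genes.sort_values(["chrom", "start"])

    de_tables: dict[str, pd.DataFrame] = {}
    for net in nets:
        in_ip = overlaps_any(genes, drs[net][drs[net]["dr_class"] == "IP"])
        in_pi = overlaps_any(genes, drs[net][drs[net]["dr_class"] == "PI"])
        pclass = np.where(in_ip, "IP", np.where(in_pi, "PI", "none"))
        repositioned = np.nonzero(pclass != "none")[0]
        others = np.nonzero(pclass == "none")[0]
        n_from_moved = min(len(repositioned),
                           int(round(config.n_de_genes * config.de_repositioned_fraction)))
        chosen_moved = rng.choice(repositioned, n_from_moved, replace=False)
        chosen_other = rng.choice(others, min(config.n_de_genes - n_from_moved, len(others)),
                                  replace=False)
        direction = np.zeros(len(genes), dtype=int)
        concordant = np.full(len(genes), False)
        for gi in chosen_moved:
            expected = -1 if pclass[gi] == "IP" else 1  # toward periphery -> down
            is_conc = rng.random() < config.concordance_rate
            direction[gi] = expected if is_conc else -expected
            concordant[gi] = is_conc
        direction[chosen_other] = rng.choice([-1, 1], len(chosen_other))
        table = pd.DataFrame({
            "direction": direction,
            "true_lfc": direction * config.de_log2fc_mean,
            "position_class": pclass,
            "concordant": concordant,
            "is_de": direction != 0,
        }, index=genes.index)
        de_tables[net] = table
    return GroundTruth(lads_by_condition=lads, drs=drs, genes=genes,
                       de_tables=de_tables, config=config)


# --------------------------------------------------------------- DamID reads

def _nb_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial counts with var = m + dispersion * m^2 (Poisson at 0)."""
    mean = np.clip(mean, 0.0, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _planted_log2(fmap: FragmentMap, lads: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    mids = fmap.midpoints()
    chroms = np.concatenate([[c] * fmap.n_fragments_chrom(c) for c in fmap.chroms])
    frag = pd.DataFrame({"chrom": chroms, "start": mids.astype(np.int64),
                         "end": mids.astype(np.int64) + 1})
    inside = overlaps_any(frag, lads)
    return np.where(inside, config.lad_log2_mean, config.nonlad_log2_mean)


def _counts_to_reads(fmap: FragmentMap, counts: np.ndarray, read_len: int,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Expand per-fragment counts to read intervals lying fully inside their
    fragment (so midpoint assignment round-trips exactly)."""
    chroms, starts, ends = [], [], []
    for chrom in fmap.chroms:
        sl = fmap.chrom_slice(chrom)
        c = counts[sl]
        fs = np.repeat(fmap.starts[chrom], c)
        fe = np.repeat(fmap.ends[chrom], c)
        span = np.maximum(fe - fs - read_len, 0)
        rs = fs + (rng.random(len(fs)) * (span + 1)).astype(np.int64)
        re = np.minimum(rs + read_len, fe)
        chroms.append(np.repeat(chrom, len(rs)))
        starts.append(rs)
        ends.append(re)
    if not chroms:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.DataFrame({"chrom": np.concatenate(chroms),
                         "start": np.concatenate(starts),
                         "end": np.concatenate(ends)})


def simulate_damid_counts(config: SimulationConfig, truth: GroundTruth, condition: str,
                          fmap: FragmentMap) -> tuple[np.ndarray, np.ndarray]:
    """Per-fragment (lamin, dam) counts for one condition.

    Dam-alone rates are proportional to fragment length (accessibility
    control); lamin rates multiply that by 2^(planted log2 + noise)."""
    if condition not in truth.lads_by_condition:
        raise KeyError(f"condition {condition!r} not present in ground truth")
    cond_idx = list(truth.config.conditions).index(condition)
    rng = config.rng(_S_READS, cond_idx)
    planted = _planted_log2(fmap, truth.lads_by_condition[condition], config)
    noise = rng.normal(0.0, config.noise_sd, fmap.n_fragments) if config.noise_sd > 0 else 0.0
    lens = fmap.fragment_lengths().astype(float)
    lenfrac = lens / lens.sum()
    dam_rate = lenfrac
    lam_w = lenfrac * np.exp2(planted + noise)
    lam_rate = lam_w / lam_w.sum()
    lamin = _nb_counts(config.reads_per_sample * lam_rate, config.dispersion, rng)
    dam = _nb_counts(config.reads_per_sample * dam_rate, config.dispersion, rng)
    return lamin, dam


def simulate_damid_reads(config: SimulationConfig, truth: GroundTruth, condition: str,
                         fmap: FragmentMap) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read interval sets (lamin sample, Dam-alone sample) for one condition."""
    lamin, dam = simulate_damid_counts(config, truth, condition, fmap)
    cond_idx = list(truth.config.conditions).index(condition)
    rng = config.rng(_S_READS, cond_idx, 99)
    return (_counts_to_reads(fmap, lamin, config.read_length_bp, rng),
            _counts_to_reads(fmap, dam, config.read_length_bp, rng))


# --------------------------------------------------------------- expression

def simulate_expression(config: SimulationConfig, truth: GroundTruth) -> dict[str, pd.DataFrame]:
    """Replicate log2-intensity matrices for the control and every NET.

    Control replicates: per-gene baseline + Gaussian replicate noise. NET
    replicates add the planted true log2FC of that NET's DE genes. Returns
    {condition: genes x replicates DataFrame}.
    """
    config.validate()
    if config.n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = config.rng(_S_EXPR)
    genes = truth.genes.index
    baseline = rng.normal(8.0, 1.5, len(genes))
    out: dict[str, pd.DataFrame] = {}
    cols = [f"rep{r + 1}" for r in range(config.n_replicates)]
    ctrl = baseline[:, None] + rng.normal(0.0, config.expr_noise_sd,
                                          (len(genes), config.n_replicates))
    out[config.control_label] = pd.DataFrame(ctrl, index=genes, columns=cols)
    for net in config.net_conditions:
        lfc = truth.de_tables[net]["true_lfc"].to_numpy()
        mat = (baseline + lfc)[:, None] + rng.normal(0.0, config.expr_noise_sd,
                                                     (len(genes), config.n_replicates))
        out[net] = pd.DataFrame(mat, index=genes, columns=cols)
    return out


def simulate_reference_program(config: SimulationConfig, truth: GroundTruth,
                               net: str, n_ref_de: int | None = None) -> pd.Series:
    """Reference-differentiation log2FC table (e.g. an iPS->hepatocyte program).

    The reference DE set overlaps the NET's DE set at ``ref_overlap_rate``
    (overlapping genes change in the same direction); the table is the mean
    log2FC over simulated replicate matrices so it carries sampling noise
    like a real fold-change table.
    """
    rng = config.rng(_S_REF)
    genes = truth.genes.index
    de = truth.de_tables[net]
    net_de = de.index[de["is_de"]]
    if n_ref_de is None:
        n_ref_de = config.n_de_genes
    n_shared = min(int(round(n_ref_de * config.ref_overlap_rate)), len(net_de))
    shared = rng.choice(net_de.to_numpy(), n_shared, replace=False)
    pool = genes.difference(pd.Index(shared))
    extra = rng.choice(pool.to_numpy(), min(n_ref_de - n_shared, len(pool)), replace=False)
    true_lfc = pd.Series(0.0, index=genes)
    true_lfc.loc[shared] = de.loc[shared, "true_lfc"]
    true_lfc.loc[extra] = rng.choice([-1.0, 1.0], len(extra)) * config.de_log2fc_mean
    n_rep = config.n_replicates
    noise = rng.normal(0.0, config.expr_noise_sd, (len(genes), 2 * n_rep))
    obs = true_lfc.to_numpy()[:, None] + noise[:, :n_rep] - noise[:, n_rep:]
    return pd.Series(obs.mean(axis=1), index=genes, name="ref_log2fc")


# --------------------------------------------------------------- writers

def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
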