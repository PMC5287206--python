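import numpy as np
import pytest

import lad_shift as ls


@pytest.fixture(scope="session")
def mini_config():
    """Small two-chromosome study used by fast integration tests."""
    return ls.SimulationConfig(
        seed=1,
        n_chromosomes=2,
        chrom_length_bp=500_000,
        n_constitutive_lads=2,
        constitutive_lad_len_bp=(80_000, 120_000),
        n_facultative_lads=3,
        facultative_lad_len_bp=(20_000, 40_000),
        n_drs_per_class=4,
        dr_len_bp=(18_000, 30_000),
        n_genes=200,
        n_de_genes=60,
        reads_per_sample=100_000,
        net_conditions=("NET29",),
    )


def run_damid_analysis(config, seed=0):
    """Simulate a study and run it through normalization, CBS, LAD and DR
    calling; returns everything downstream tests need."""
    sequences, fmap = ls.simulate_genome(config)
    truth = ls.simulate_truth(config)
    raw = {}
    for cond in config.conditions:
        lam, dam = ls.simulate_damid_counts(config, truth, cond, fmap)
        raw[cond] = ls.log2_ratio(
            ls.CountTrack(lam, label=f"{cond}/lamin", fragment_map=fmap),
            ls.CountTrack(dam, label=f"{cond}/dam", fragment_map=fmap),
            condition=cond,
        )
    tracks = {t.condition: t for t in ls.quantile_normalize(list(raw.values()))}
    segments, lads = {}, {}
    for i, cond in enumerate(config.conditions):
        segments[cond] = ls.cbs_segment(tracks[cond], seed=[seed, i])
        lads[cond] = ls.call_lads(segments[cond], condition=cond)
    drs = {}
    control = config.control_label
    for net in config.net_conditions:
        windows = ls.union_windows(segments[control], segments[net])
        mc = ls.window_means(windows, tracks[control])
        mn = ls.window_means(windows, tracks[net])
        drs[net] = ls.call_drs(windows, mc, mn, lads[control], lads[net])
    return {
        "config": config, "fmap": fmap, "truth": truth, "tracks": tracks,
        "segments": segments, "lads": lads, "drs": drs,
    }


@pytest.fixture(scope="session")
def mini_run(mini_config):
    return run_damid_analysis(mini_config)


@pytest.fixture(scope="session")
def standard_run():
    """The standard simulation: 10 Mb genome, ~39k fragments, planted log2
    +1 inside / -1 outside LADs, per-fragment noise sd 0.5, 20 planted IP
    and PI regions per NET condition."""
    import time

    t0 = time.time()
    result = run_damid_analysis(ls.SimulationConfig(seed=1))
    result["elapsed_s"] = time.time() - t0
    return result


@pytest.fixture
def rng():
    return np.random.default_rng(0)
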