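import pytest

from polpause import synthetic_data as sd


@pytest.fixture(scope="session")
def small_cfg() -> sd.SynthConfig:
    """Reduced-scale study conditions for fast unit tests."""
    return sd.SynthConfig(
        seed=11,
        n_paused_active=80, n_nonpaused_active=60, n_inactive=60,
        chrom_sizes={"chrA": 2_000_000},
        n_promoter_peaks=30, n_intergenic_peaks=20,
        n_intergenic_affected=10, n_affected=15,
    )


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    genes, seqs, truth = sd.simulate_genome(small_cfg)
    return {"genes": genes, "seqs": seqs, "truth": truth}


@pytest.fixture(scope="session")
def small_tracks(small_cfg, small_genome):
    tracks = {}
    for cond in ("control", "kd"):
        for rep in (1, 2):
            t = sd.simulate_groseq_track(small_genome["genes"],
                                         small_genome["truth"]["genes"],
                                         small_cfg, cond, rep)
            tracks[t.label] = t
    return tracks
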