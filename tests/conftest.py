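import numpy as np
import pandas as pd
import pytest

from ramscan import (
    CountMatrix,
    PipelineConfig,
    count_reads,
    random_truth,
    simulate_genome,
    simulate_methylation_reads,
    simulate_sample_sheet,
)


def nb_count_matrix(rng, n_windows, n_samples, mean, phi):
    """Direct NB counts (gamma-Poisson), equal library sizes."""
    if phi > 0:
        lam = rng.gamma(1.0 / phi, phi * mean, size=(n_windows, n_samples))
    else:
        lam = np.full((n_windows, n_samples), float(mean))
    counts = rng.poisson(lam)
    windows = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_windows) * 50,
            "end": np.arange(n_windows) * 50 + 100,
        }
    )
    return CountMatrix(
        windows=windows,
        samples=[f"s{i:02d}" for i in range(n_samples)],
        counts=counts,
        lib_sizes=np.full(n_samples, counts.sum() / n_samples),
    )


def spiked_dataset(seed, n_spikes=30, log2fc=2.0, windows_per_spike=4,
                   mean_length_bp=400_000, dispersion=0.1, comparison="nd_vs_high"):
    """One full synthetic methylation dataset with spiked truth.

    Depth is chosen so the per-window mean count is ~50.
    """
    genome, track = simulate_genome(
        n_chroms=1, mean_length_bp=mean_length_bp, cgi_density=5e-5,
        gene_density=1e-5, repeat_fraction=0.3, seed=seed,
    )
    sheet = simulate_sample_sheet(6, seed=seed)
    truth = random_truth(
        genome, n_spikes=n_spikes, log2fc=log2fc,
        windows_per_spike=windows_per_spike, comparison=comparison, seed=seed,
    )
    depth = 25 * sum(-(-L // 50) for L in genome.chrom_lengths)
    reads = simulate_methylation_reads(
        genome, track, sheet, depth_per_sample=depth, cgi_enrichment_factor=1.0,
        truth=truth, dispersion=dispersion, seed=seed,
    )
    cm = count_reads(genome, reads)
    return genome, track, sheet, truth, cm


def spike_metrics(truth, rams, window_size=100):
    """(recovery over truth windows, false fraction over called windows).

    Called windows partially overlapping a spiked region carry a diluted
    true effect and count as neither recovered nor false.
    """
    truth_keys = {(w.chrom, w.start) for w in truth.spiked_windows}
    regions = truth.spiked_regions()

    def overlaps(c, s):
        return any(r.chrom == c and s < r.end and r.start < s + window_size for r in regions)

    called = set(zip(rams["chrom"].astype(str), rams["start"]))
    recovery = len(called & truth_keys) / len(truth_keys) if truth_keys else np.nan
    false = [k for k in called if not overlaps(*k)]
    false_frac = len(false) / len(called) if called else 0.0
    return recovery, false_frac


@pytest.fixture(scope="session")
def small_genome():
    return simulate_genome(
        n_chroms=2, mean_length_bp=200_000, cgi_density=5e-5,
        gene_density=2e-5, repeat_fraction=0.3, seed=5,
    )
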