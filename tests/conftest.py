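import numpy as np
import pytest

from darkcov.intervals import GenomicInterval
from darkcov.synthetic import generate_cohort, write_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort under the default study conditions."""
    return generate_cohort(seed=11)


@pytest.fixture(scope="session")
def cohort_paths(tmp_path_factory, default_cohort):
    """The default cohort written to disk (all pipeline input formats)."""
    out = tmp_path_factory.mktemp("cohort")
    return write_cohort(default_cohort, out)


def per_base_cover(intervals, chrom_lengths):
    """Brute-force per-base boolean coverage arrays, one per chromosome."""
    cover = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
    for iv in intervals:
        cover[iv.chrom][iv.start : iv.end] = True
    return cover


def random_intervals(rng, n, chroms, chrom_len, max_len=200):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, chrom_len - 1))
        length = int(rng.integers(1, max_len + 1))
        out.append(GenomicInterval(chrom, start, min(start + length, chrom_len)))
    return out
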