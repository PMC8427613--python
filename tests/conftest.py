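import numpy as np
import pytest

from cnsig.genome import GenomeBuild
from cnsig.segments import Segment, SegmentProfile


@pytest.fixture(scope="session")
def toy_genome():
    """A tiny 22-autosome genome (Mb scale) for brute-force comparisons."""
    lengths = {str(i): 1_000_000 + 20_000 * i for i in range(1, 23)}
    centromeres = {str(i): lengths[str(i)] // 2 for i in range(1, 23)}
    return GenomeBuild(name="toy", lengths=lengths, centromeres=centromeres)


@pytest.fixture(scope="session")
def diploid_profile(toy_genome):
    """Whole-genome single-segment diploid profile."""
    segs = [Segment(chrom=c, start=0, end=toy_genome.lengths[c], cn=2.0)
            for c in toy_genome.chromosomes]
    return SegmentProfile(sample_id="diploid", segments=segs)


def random_profile(genome, rng, max_segments=8, n_chromosomes=4):
    """Random small profile on the first few chromosomes (for oracles)."""
    segs = []
    for chrom in genome.chromosomes[:n_chromosomes]:
        length = genome.lengths[chrom]
        k = int(rng.integers(1, max_segments + 1))
        cuts = np.sort(rng.choice(np.arange(1, length), size=k - 1, replace=False)) if k > 1 else np.array([], dtype=int)
        bounds = [0, *cuts.tolist(), length]
        for s, e in zip(bounds[:-1], bounds[1:]):
            segs.append(Segment(chrom=chrom, start=int(s), end=int(e),
                                cn=float(rng.choice([0.0, 1.0, 1.7, 2.0, 2.4, 3.0, 4.0]))))
    return SegmentProfile(sample_id="rand", segments=segs)
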