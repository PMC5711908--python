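import numpy as np
import pytest

from hapdemog.seqio import Alignment, SampleRecord


def toy_alignment(seqs, regions=None, statuses=None, years=None,
                  lons=None, lats=None):
    """Build an Alignment from a list of sequence strings."""
    n = len(seqs)
    samples = [
        SampleRecord(
            sample_id=f"s{i + 1}",
            region=regions[i] if regions else "R",
            status=statuses[i] if statuses else "native",
            year=years[i] if years else None,
            lon=lons[i] if lons else None,
            lat=lats[i] if lats else None,
        )
        for i in range(n)
    ]
    sites = np.array([list(s) for s in seqs], dtype="U1")
    return Alignment(samples=samples, sites=sites)


@pytest.fixture
def two_pool_alignment():
    from hapdemog import synthetic

    spec = synthetic.SequenceSpec(
        L=400,
        fixed_differences=8,
        groups=(
            synthetic.SequenceGroupSpec(
                name="PoolA", n=12, pool="A", theta0=2.0, theta1=2.0, tau=0.0
            ),
            synthetic.SequenceGroupSpec(
                name="PoolB", n=14, pool="B", theta0=2.0, theta1=2.0, tau=0.0,
                status="invasive", center=(10.0, 50.0),
            ),
        ),
    )
    return synthetic.make_sequence_dataset(spec, seed=11)
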