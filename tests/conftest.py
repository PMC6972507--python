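import numpy as np
import pytest

from nanobreak import Config
from nanobreak import simulate as sim


@pytest.fixture
def cfg():
    return Config()


@pytest.fixture(scope="session")
def small_ref():
    """Two 100 kb contigs; big enough for split reads with 200 bp flanks."""
    return sim.make_reference({"chrA": 100_000, "chrB": 100_000}, seed=11)


def make_translocation(ref, pos_a=50_000, pos_b=60_000, del_a=0, del_b=0,
                       ins_a=0, ins_b=0, carrier=2):
    haps = sim.diploid_from_reference(ref)
    spec = sim.EventSpec(kind="reciprocal_translocation", chrom_a="chrA",
                         pos_a=pos_a, chrom_b="chrB", pos_b=pos_b,
                         junction_del_a=del_a, junction_del_b=del_b,
                         junction_ins_a=ins_a, junction_ins_b=ins_b,
                         carrier_haplotype=carrier)
    der, junctions, deleted = sim.apply_rearrangement(
        ref, haps[carrier - 1], spec, rng=np.random.default_rng(99))
    return der, junctions, deleted


@pytest.fixture(scope="session")
def noiseless_sam(small_ref, tmp_path_factory):
    """Carrier-only noiseless dataset over the session reference."""
    der, junctions, _ = make_translocation(small_ref)
    reads = sim.simulate_reads([der], small_ref, depth=10, seed=21,
                               error_model=sim.ErrorModel(0, 0, 0))
    path = tmp_path_factory.mktemp("noiseless") / "aln.sam"
    sim.simulate_alignments(reads, [der], small_ref, str(path))
    return {"sam": str(path), "reads": reads, "haplotype": der,
            "junctions": junctions, "ref": small_ref}
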