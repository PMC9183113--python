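import numpy as np
import pytest

from satscout import simrep
from satscout.rdnalink import annotate_rdna, classify_copies, delineate_igs
from satscout.aligncore import PRESETS, local_search


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1)


@pytest.fixture(scope="session")
def monomer237():
    """A fixed random 237 bp monomer (no internal structure)."""
    return simrep.random_seq(237, np.random.default_rng(42))


@pytest.fixture(scope="session")
def dimeric_monomer():
    """A 237 bp monomer built from 111+126 bp subunits at ~70% identity."""
    return simrep.make_family_monomer(
        simrep.MonomerFamilySpec("fam", (111, 126)), np.random.default_rng(1))


@pytest.fixture(scope="session")
def demo_genome():
    """The bundled demo scenario rendered once: (chroms, manifest, spec)."""
    spec = simrep.demo_spec(seed=1)
    chroms, manifest = simrep.build_genome(spec)
    return chroms, manifest, spec


@pytest.fixture(scope="session")
def rdna_scenario(demo_genome):
    """Annotated rDNA cluster of the demo genome (expensive; shared).

    Returns units, IGS regions (with embedded copies populated), the
    labelled repeat hits of the derived family, and the truth manifest.
    """
    chroms, manifest, spec = demo_genome
    refs = simrep.surrogate_rrna_refs()
    units = annotate_rdna(chroms, {k: refs[k] for k in ("18S", "5.8S", "26S")})
    igs = delineate_igs(units)
    monomer = manifest.by_kind("monomer_refs")[0]["sequences"]["delCS237like"]
    hits = []
    for chrom, seq in chroms.items():
        hits.extend(local_search(monomer, seq, PRESETS["relaxed"],
                                 subject_id=chrom))
    labeled = classify_copies(hits, igs, family="delCS237like")
    return {"units": units, "igs": igs, "labeled": labeled,
            "manifest": manifest, "chroms": chroms}
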