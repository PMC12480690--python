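import numpy as np
import pandas as pd
import pytest

import splicehex as sx
from splicehex import synthio


@pytest.fixture(scope="session")
def model():
    return sx.TrueStrengthModel.distance_decay(seed=11)


@pytest.fixture(scope="session")
def small_cohort(model):
    """A small replicated cohort with some hexamer-switching variants."""
    config = sx.SynthConfig(n_genes=15, introns_per_gene=2, n_genotypes=30,
                            replicates_per_genotype=3, read_depth_mean=60,
                            causal_fraction=0.3, seed=11)
    genome, sites = synthio.generate_genome(config, model)
    variants, dosages = synthio.simulate_genotypes(config, sites, genome,
                                                   n_background=120)
    truth = synthio.true_sse(sites, model, genome, variants, dosages)
    matrix = synthio.simulate_junction_counts(truth, config, sites)
    return {"config": config, "model": model, "genome": genome, "sites": sites,
            "variants": variants, "dosages": dosages, "truth": truth,
            "matrix": matrix}


def make_sites(records) -> pd.DataFrame:
    df = pd.DataFrame.from_records(records)
    return df.set_index("site_id")


@pytest.fixture
def toy_genome():
    """Hand-written two-contig genome with one plus- and one minus-strand
    donor whose transcribed hexamers are both GTAAGC."""
    #                  1-based:  123456789...
    chr1 = "CCCAGGTAAGCTTTTTACAGGG"  # + donor at 6 (GTAAGC), acceptor at 20 (ACAG -> AG at 19,20)
    chr2 = "AAGCTTACCTGAAA"  # - strand donor: revcomp(GCTTAC)=GTAAGC, G at pos 9
    return {"chr1": chr1, "chr2": chr2}
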