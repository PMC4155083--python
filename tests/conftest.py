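import numpy as np
import pytest

from synblock.core_model import Chromosome, FamilySet, Gene, Genome
from synblock.simulator import figure3_fixture
from synblock.tandem_mhp import build_mhp, rewrite_in_tbs


@pytest.fixture(scope="session")
def fig3():
    """The worked dot-plot example: (genome_a, genome_b, families)."""
    return figure3_fixture()


@pytest.fixture(scope="session")
def fig3_mhp(fig3):
    ga, gb, fams = fig3
    ca = rewrite_in_tbs(ga.chromosomes[0], fams)
    cb = rewrite_in_tbs(gb.chromosomes[0], fams)
    return build_mhp(ca, cb)


def random_genome_pair(seed: int, n_genes: int = 40, n_shared: int = 25):
    """Small random genome pair sharing n_shared 1:1 families.

    Gene orders are independent random permutations, so any diagonals are
    chance diagonals; used by property tests.
    """
    rng = np.random.default_rng(seed)
    fams = {f"F{i}": set() for i in range(n_shared)}

    def build(species):
        names = []
        for i in range(n_genes):
            name = f"{species}{i}"
            names.append(name)
            if i < n_shared:
                fams[f"F{i}"].add(name)
        order = rng.permutation(n_genes)
        genes = [Gene(names[int(k)], int(rng.choice([1, -1]))) for k in order]
        # split into 1-2 chromosomes
        cut = int(rng.integers(1, n_genes))
        chroms = [Chromosome(f"{species}_c1", genes[:cut])]
        if cut < n_genes:
            chroms.append(Chromosome(f"{species}_c2", genes[cut:]))
        return Genome(species, chroms)

    ga, gb = build("a"), build("b")
    return ga, gb, FamilySet(fams)
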