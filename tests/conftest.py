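import numpy as np
import pytest

import phenoblup as pb


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced study: 2 pools x 3 families x 6 lines, 150 markers."""
    return pb.SimConfig(
        seed=42,
        families_per_pool=3,
        lines_per_family=6,
        n_chromosomes=5,
        markers_per_chromosome=30,
        hybrids_per_parent=3,
        wavelength_grid=np.linspace(400.0, 2400.0, 60),
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """Genotypes, design and phenotypes simulated once per session."""
    geno, dfam, ffam = pb.simulate_genotypes(small_cfg)
    dents = [l for l, p in zip(geno.line_ids, geno.pools) if p == "dent"]
    flints = [l for l, p in zip(geno.line_ids, geno.pools) if p == "flint"]
    design = pb.simulate_factorial(dents, flints, small_cfg, dfam, ffam)
    phen, realized = pb.simulate_hybrid_phenotypes(design, geno, small_cfg)
    return {
        "cfg": small_cfg,
        "geno": geno,
        "design": design,
        "phen": phen,
        "realized": realized,
        "dents": dents,
        "flints": flints,
        "dfam": dfam,
        "ffam": ffam,
    }


@pytest.fixture(scope="session")
def small_kernels(small_dataset):
    geno, design = small_dataset["geno"], small_dataset["design"]
    kd = pb.vanraden_gca_kinship(geno.subset_pool("dent"), role="GCA_dent")
    kf = pb.vanraden_gca_kinship(geno.subset_pool("flint"), role="GCA_flint")
    ks = pb.repair_psd(pb.sca_kernel(kd, kf, design))
    return {"gca_dent": kd, "gca_flint": kf, "sca": ks}


def random_kinship(n, m, seed, ids=None, role="GCA_dent"):
    """Well-conditioned random kinship-like kernel for engine tests."""
    rng = np.random.default_rng(seed)
    M = rng.standard_normal((n, m))
    k = M @ M.T / m
    return pb.KernelMatrix(
        k, ids or [f"g{i}" for i in range(n)], "genomic", role
    )
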