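import numpy as np
import pandas as pd
import pytest

from nabsel.pedigree import build_pedigree
from nabsel.simulate import LocusSpec, default_config, run_experiment


def random_pedigree(n_founders, n_offspring, generations, seed, inbred=False):
    """Random discrete-generation pedigree for relationship-matrix tests."""
    rng = np.random.default_rng(seed)
    rows = [
        {"animal": f"F{i}", "sire": "0", "dam": "0",
         "sex": "M" if i % 2 else "F", "generation": 0, "line": "base"}
        for i in range(n_founders)
    ]
    males = [f"F{i}" for i in range(1, n_founders, 2)]
    females = [f"F{i}" for i in range(0, n_founders, 2)]
    k = 0
    for g in range(1, generations + 1):
        new_m, new_f = [], []
        for _ in range(n_offspring):
            s = str(rng.choice(males))
            d = str(rng.choice(females))
            if not inbred:
                tries = 0
                while d == s and tries < 10:
                    d = str(rng.choice(females))
                    tries += 1
            name = f"A{k}"
            k += 1
            sex = "M" if rng.random() < 0.5 else "F"
            rows.append(
                {"animal": name, "sire": s, "dam": d, "sex": sex,
                 "generation": g, "line": "high"}
            )
            (new_m if sex == "M" else new_f).append(name)
        males = new_m or males
        females = new_f or females
    return build_pedigree(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_recovery_sim():
    """One no-locus, no-selection dataset (~1,100 records) shared by model tests."""
    cfg = default_config(
        n_base=300,
        generations=2,
        generation_sizes=(400, 400),
        locus=LocusSpec(p0=0.45, genotype_values={}),
        select=False,
        sires_selected=20,
        dams_selected=40,
    )
    return run_experiment(cfg, seed=20)


@pytest.fixture(scope="session")
def divergent_sim():
    """One small divergent-selection run with the major locus segregating."""
    cfg = default_config(
        n_base=500,
        generations=4,
        generation_sizes=(400, 400, 400, 400),
        sires_selected=15,
        dams_selected=30,
    )
    return run_experiment(cfg, seed=21)
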