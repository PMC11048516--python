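import numpy as np
import pandas as pd
import pytest

from octacrmb import SyntheticParams, generate_sample
from octacrmb.metrics import CRMB_NAMES


@pytest.fixture(scope="session")
def default_sample():
    """Default-condition synthetic SCP/DCP pair with truth masks."""
    return generate_sample(SyntheticParams(seed=1))


@pytest.fixture(scope="session")
def standard_scp_sample():
    """The standard large-vessel fixture: 4 radial 50-µm vessels (0.95)
    over a 10-µm capillary mesh (0.6)."""
    return generate_sample(
        SyntheticParams(
            seed=7,
            n_large_vessels=4,
            large_vessel_width_um=50.0,
            large_vessel_intensity=0.95,
            capillary_width_um=10.0,
            capillary_intensity=0.6,
        )
    )


def random_crmb_table(seed: int, n: int = 73, signal: bool = False) -> pd.DataFrame:
    """Subject-level table with Gaussian placeholder biomarkers."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(n, len(CRMB_NAMES))), columns=CRMB_NAMES)
    df["group"] = rng.choice(["normal", "RVO"], n)
    df["age"] = rng.normal(50, 12, n)
    df["sex"] = rng.choice(["men", "women"], n)
    df["eye"] = rng.choice(["right", "left"], n)
    for c in ("diabetes", "hypertension", "hyperlipidaemia", "atherosclerosis"):
        df[c] = rng.uniform(size=n) < 0.2
    df["bcva_initial"] = rng.normal(0.7, 0.2, n)
    if signal:
        df.loc[df["group"] == "RVO", "PDCS"] -= 1.5
        df.loc[df["group"] == "RVO", "FAS"] += 1.5
    df["id"] = [f"S{i:03d}" for i in range(n)]
    return df
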