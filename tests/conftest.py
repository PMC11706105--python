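import numpy as np
import pytest

from revscreen.containers import DiseaseProfile, DrugProfile, SignatureProfile


@pytest.fixture
def toy_profile() -> DiseaseProfile:
    """The worked three-gene example used throughout the scoring tests."""
    return DiseaseProfile({"g1": 2.0, "g2": -1.0, "g3": 1.0})


@pytest.fixture
def toy_drug() -> DrugProfile:
    return DrugProfile("toydrug", {"g1": -1.0, "g2": 0.5, "g3": 1.0}, n_signatures=1)


@pytest.fixture
def wide_profile() -> DiseaseProfile:
    """A 200-gene profile with LFCs clearing the usual |LFC| > 1 threshold."""
    rng = np.random.default_rng(42)
    lfc = rng.uniform(1.0, 4.0, size=200) * rng.choice([-1, 1], size=200)
    return DiseaseProfile({f"G{i:04d}": float(v) for i, v in enumerate(lfc)})


def inverse_signature(profile: DiseaseProfile, sig_id: str = "inv", drug: str = "inverse",
                      library: str = "TestLib") -> SignatureProfile:
    return SignatureProfile(sig_id, drug, library, {g: -v for g, v in profile.entries.items()})
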