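import numpy as np
import pytest

from knockmore import Pwm


def make_pwm(name: str, consensus: str, p: float = 0.94) -> Pwm:
    """Near-deterministic PWM whose argmax spells ``consensus``."""
    off = (1.0 - p) / 3
    mat = np.full((len(consensus), 4), off)
    for i, base in enumerate(consensus):
        mat[i, "ACGT".index(base)] = p
    return Pwm(name, mat)


@pytest.fixture(scope="session")
def pwm_library() -> dict[str, Pwm]:
    # non-palindromic consensi so strand assignment is unambiguous
    consensi = {"TFA": "TGACGTAA", "TFB": "CACGTGAC", "TFC": "GGGCGGGA",
                "TFD": "TTTCGCGC", "TFE": "ATGCAAAT"}
    return {name: make_pwm(name, cons) for name, cons in consensi.items()}
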