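import numpy as np
import pandas as pd
import pytest

from grnkit.catalog import Lexicon
from grnkit.coexpression import ExpressionMatrix


@pytest.fixture
def lexicon():
    return Lexicon(
        {
            "STAT3": "TF",
            "POU3F2": "TF",
            "TCF4": "TF",
            "OGG1": "GENE",
            "CDK6": "GENE",
            "FMR1": "GENE",
            "hsa-miR-298": "MIRNA",
            "hsa-miR-590-3p": "MIRNA",
            "hsa-miR-301b": "MIRNA",
        },
        aliases={"BRN2": "POU3F2", "E2-2": "TCF4"},
    )


@pytest.fixture
def small_expr():
    """6 entities x 20 samples (14 control + 2 per MS condition)."""
    rng = np.random.default_rng(7)
    samples = [f"S{i}" for i in range(20)]
    conds = ["CONTROL"] * 14 + ["RRMS", "RRMS", "PPMS", "PPMS", "SPMS", "SPMS"]
    entities = ["STAT3", "OGG1", "CDK6", "POU3F2", "hsa-miR-298", "hsa-miR-590-3p"]
    values = pd.DataFrame(
        rng.lognormal(5, 0.5, size=(len(entities), len(samples))),
        index=entities,
        columns=samples,
    )
    return ExpressionMatrix(values, pd.Series(conds, index=samples))
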