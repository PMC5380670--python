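import io

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from camfam import ExpressionAtlas, GeneratorConfig, make_cam_cohort

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (reference CaM, isoforms, 19 CMLs, decoys)."""
    return make_cam_cohort(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def ref(cohort):
    records, truth = cohort
    return records[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# Published expression census for the L. japonicus CaM/CML family:
# per-gene values over six organs and three rhizobia-inoculation conditions.
CENSUS_ATLAS_TSV = """\
gene\tSeeds\tFlower\tLeaf\tStem\tRoot\tNodule\tR3W Un\tR3W In7\tR3W In21
LjCaM1-1\t3598.2\t3969.61\t3041.73\t3661.08\t2940.14\t9322.85\t2491.62\t4373.77\t4000.25
LjCaM1-2\t3598.2\t3969.61\t3041.73\t3661.08\t2940.14\t9322.85\t2491.62\t4373.77\t4000.25
LjCaM1-3\t3598.2\t3969.61\t3041.73\t3661.08\t2940.14\t9322.85\t2491.62\t4373.77\t4000.25
LjCaM2\t3598.2\t3969.61\t3041.73\t3661.08\t2940.14\t9322.85\t2491.62\t4373.77\t4000.25
LjCaM3-1\t317.61\t27.37\t35.53\t595.56\t749.8\t2617.01\t299.02\t474.29\t543.74
LjCaM3-2\t317.61\t27.37\t35.53\t595.56\t749.8\t2617.01\t299.02\t474.29\t543.74
LjCaM4\t317.61\t27.37\t35.53\t595.56\t749.8\t2617.01\t299.02\t474.29\t543.74
LjCML1\t712.85\t1373.57\t934.38\t946.28\t276.82\t174.27\t571.21\t236.49\t829.42
LjCML2\t79.4\t181.68\t122.35\t402.88\t467.25\t358.14\t260.37\t208.24\t260.17
LjCML3\t137.81\t835.28\t172.57\t337.04\t593.82\t222.81\t1001.67\t469.99\t1348.77
LjCML4\t79.4\t181.68\t122.35\t402.88\t467.25\t358.14\t260.37\t208.24\t260.17
LjCML5\t79.4\t181.68\t122.35\t402.88\t467.25\t358.14\t260.37\t208.24\t260.17
LjCML6\t296.31\t229.89\t57.11\t571.28\t653.1\t2203.14\t436.67\t856.92\t702.97
LjCML7\t247.68\t563.04\t616.6\t551.49\t597.16\t1546.73\t441.23\t1170.35\t521.81
LjCML8\t14.53\t14.44\t11.41\t11.77\t18.22\t12.7\t15.86\t14.79\t13.7
LjCML9\t28.7\t24.2\t25.06\t37.74\t26.26\t24.93\t34.82\t31.05\t54.5
LjCML10\t28.7\t24.2\t25.06\t37.74\t26.26\t24.93\t34.82\t31.05\t54.5
LjCML11\t11.71\t1643.78\t12.83\t54.74\t1009.61\t589.54\t669.34\t617.9\t853.71
LjCML12\t296.31\t229.89\t57.11\t571.28\t653.1\t2203.14\t436.67\t856.92\t702.97
LjCML13\t156.66\t180.86\t137.16\t259.04\t350.5\t117.8\t367.95\t288.23\t381.15
LjCML14\t28.38\t28.81\t29.2\t45.01\t1124.8\t313.48\t1046.65\t476.64\t761.15
LjCML15\t28.7\t24.2\t25.06\t37.74\t26.26\t24.93\t34.82\t31.05\t54.5
LjCML16\t11.71\t1643.78\t12.83\t54.74\t1009.61\t589.54\t669.34\t617.9\t853.71
LjCML17\t14.12\t10.07\t9.68\t36.06\t10.81\t12.82\t24.37\t19.56\t104.25
LjCML18\t605.28\t419.78\t88.52\t146.93\t199.36\t143.35\t172.24\t161.62\t143.54
LjCML19\t1485.3\t1046.29\t685.67\t572.63\t664.97\t1293.65\t429.36\t441.95\t442.5
"""

ORGANS = ["Seeds", "Flower", "Leaf", "Stem", "Root", "Nodule"]


@pytest.fixture(scope="session")
def census_atlas():
    import pandas as pd

    return ExpressionAtlas(pd.read_csv(io.StringIO(CENSUS_ATLAS_TSV), sep="\t", index_col=0))
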