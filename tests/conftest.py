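import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# Sample rows of the tabular record format (tab-separated, 13 columns).
SAMPLE_RECORD_ROWS = """\
Tester\tEvent\tMinutes\tSeconds\tChannel 1\tChannel 2\tChannel 3\tChannel 4\tChannel 5\tChannel 6\tChannel 7\tChannel 8\tBaseline
Number 01\t1\t3.511\t210.633\t33.925\t10.482\t36.855\t-1.352\t5.072\t7.101\t47.675\t-135.587\t-738.123
Number 01\t1\t3.511\t210.641\t25.359\t5.410\t41.251\t11.158\t12.172\t17.921\t74.387\t-129.163\t-738.123
Number 01\t1\t3.511\t210.648\t35.954\t31.784\t50.719\t32.798\t27.388\t29.417\t64.920\t-93.322\t-738.123
Number 01\t1\t3.511\t210.656\t6.875\t41.251\t32.798\t43.618\t26.712\t36.179\t81.826\t-66.610\t-738.123
Number 01\t1\t3.511\t210.664\t53.085\t70.330\t78.445\t78.445\t66.948\t59.848\t120.710\t-34.827\t-738.123
Number 01\t1\t3.511\t210.672\t63.342\t68.639\t74.049\t66.948\t65.934\t61.877\t113.271\t-3.381\t-738.123
Number 01\t1\t3.511\t210.680\t84.869\t104.818\t130.178\t125.782\t113.271\t113.948\t159.594\t29.079\t-738.123
Number 01\t1\t3.511\t210.688\t168.385\t151.479\t197.802\t160.609\t167.709\t138.292\t180.220\t51.395\t-738.123
Number 01\t1\t3.512\t210.695\t194.759\t149.789\t201.860\t160.270\t192.392\t152.494\t207.608\t104.480\t-738.123
Number 01\t1\t3.512\t210.703\t257.875\t200.507\t253.593\t218.090\t234.658\t196.788\t234.996\t143.026\t-738.123
Number 01\t1\t3.512\t210.711\t238.377\t187.658\t207.270\t184.277\t180.220\t170.752\t183.263\t123.415\t-738.123
Number 12\t9\t23.071\t1384.227\t-28.966\t-75.063\t-11.158\t-52.747\t-1.014\t-29.417\t26.374\t-7.439\t-738.123
"""

#: Channel voltages of the first sample row above, in column order.
SAMPLE_ROW1_VOLTAGES = (
    33.925, 10.482, 36.855, -1.352, 5.072, 7.101, 47.675, -135.587,
)


@pytest.fixture
def sample_record_file(tmp_path):
    path = tmp_path / "records.tsv"
    path.write_text(SAMPLE_RECORD_ROWS)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_epoch(rng):
    """A 2-second, 8-channel epoch of band-limited noise."""
    from eegrhythm import Epoch

    return Epoch(
        tester_id=1,
        event_id=1,
        task_label="online payment",
        voltages=rng.normal(scale=30.0, size=(256, 8)),
        fs=128.0,
    )


def make_recording(event_ids, rng, fs=128.0, tester_id=1):
    """Helper: a recording with the given per-sample event labels."""
    from eegrhythm import Recording

    event_ids = np.asarray(event_ids, dtype=int)
    n = len(event_ids)
    v = rng.normal(scale=20.0, size=(n, 8))
    return Recording(
        tester_id=tester_id,
        event_ids=event_ids,
        time_s=np.arange(n) / fs,
        voltages=v,
        baseline=v.mean(axis=1),
        fs=fs,
    )
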