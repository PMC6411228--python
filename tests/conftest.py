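import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def workdir(tmp_path):
    """A fresh working root for one workflow run."""
    d = tmp_path / "wd"
    d.mkdir()
    return d


@pytest.fixture
def run_wf(workdir):
    """Parse inline workflow text and run it in the working root."""
    from polyflow import parse_script, run

    def _run(text, workflow=None, targets=None, **kw):
        kw.setdefault("workdir", workdir)
        return run(parse_script(text), workflow=workflow, targets=targets, **kw)

    return _run
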