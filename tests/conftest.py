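import pytest

from carekg.corpus import StopList
from carekg.locations import Gazetteer
from carekg.pipeline import PipelineConfig, run_pipeline
from carekg.synth import SynthConfig, SynthFixture, generate_fixture


@pytest.fixture(scope="session")
def stops() -> StopList:
    return StopList.default()


@pytest.fixture(scope="session")
def small_fixture() -> SynthFixture:
    """Small planted-structure corpus shared by KG/query tests."""
    return generate_fixture(SynthConfig(n_docs=80, seed=7))


def gazetteer_from_rows(rows, stops) -> Gazetteer:
    import csv
    import io

    buf = io.StringIO()
    w = csv.DictWriter(buf, fieldnames=["kind", "key", "city", "province"])
    w.writeheader()
    for r in rows:
        w.writerow(r)
    buf.seek(0)
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as tmp:
        p = Path(tmp) / "gaz.csv"
        p.write_text(buf.getvalue())
        return Gazetteer.from_csv(p, stops)


@pytest.fixture(scope="session")
def small_pipeline(small_fixture, stops):
    """Full pipeline run on the small fixture (the 'standard fixture' of the
    integration tests)."""
    gaz = gazetteer_from_rows(small_fixture.gazetteer_rows, stops)
    cfg = PipelineConfig(K0=3, topic_threshold=300, seed=7)
    return run_pipeline(
        small_fixture.documents,
        small_fixture.lexicon_entries,
        gaz,
        small_fixture.labeled,
        cfg,
        stops,
    )
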