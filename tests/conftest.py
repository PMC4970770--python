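import pytest

import trichosurvey as ts


def _sample(sid, region="Hangzhou", province="Zhejiang", zone="S", season="summer",
            crop="rice", colonies=100):
    return ts.SurveySample(
        sample_id=sid, region=region, province=province, climate_zone=zone,
        season=season, crop=crop, total_fungal_colonies=colonies,
    )


@pytest.fixture
def make_sample():
    return _sample


@pytest.fixture
def tiny_survey():
    """Four samples, two provinces, six isolates of two species — small
    enough that every statistic can be checked by hand."""
    samples = [
        _sample("A01", "Hangzhou", "Zhejiang", "S", "summer", "rice", 50),
        _sample("A02", "Hangzhou", "Zhejiang", "S", "spring", "wheat", 40),
        _sample("B01", "Jinan", "Shandong", "T", "summer", "maize", 60),
        _sample("B02", "Jinan", "Shandong", "T", "autumn", "rice", 30),
    ]
    isolates = [
        ts.IsolateRecord("A01.1", "A01", "T. hamatum", "A01.1", "ham1"),
        ts.IsolateRecord("A01.2", "A01", "T. hamatum", "A01.2", "ham2"),
        ts.IsolateRecord("A01.3", "A01", "T. harzianum", "A01.3", "harz1"),
        ts.IsolateRecord("B01.1", "B01", "T. harzianum", "B01.1", "harz1"),
        ts.IsolateRecord("B01.2", "B01", "T. harzianum", "B01.2", "harz1"),
        ts.IsolateRecord("B02.1", "B02", "T. hamatum", "B02.1", "ham1"),
    ]
    ts.attach_isolates(samples, isolates)
    return samples, isolates


@pytest.fixture(scope="session")
def small_sim():
    """A survey-shaped simulation small enough for fast tests (~680
    isolates) but large enough that all common haplotypes appear."""
    config = ts.published_survey_config(n_samples=240, seed=11)
    return ts.simulate_survey(config, seed=11)
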