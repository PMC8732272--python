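import datetime as dt
import math

import pytest
from hypothesis import given, strategies as st

from tracerlake.data_model import (
    Basis,
    CompartmentSample,
    Compartment,
    Dataset,
    DetectionPolicy,
    FishObservation,
    IsotopeChannel,
    Species,
    StudyCalendar,
    Substitution,
    Units,
    censor_spike,
    dry_to_wet,
    open_water_annual_mean,
    read_dataset,
    write_dataset,
)
from tracerlake.errors import SchemaError, ValidationError

from conftest import make_fish, make_sample


class TestDryToWet:
    def test_invertebrate_factor(self):
        assert dry_to_wet(200.0, 0.15) == pytest.approx(30.0)

    def test_identity(self):
        assert dry_to_wet(123.4, 1.0) == 123.4

    def test_zero(self):
        assert dry_to_wet(0.0, 0.4) == 0.0

    @pytest.mark.parametrize("dwp", [0.0, -0.1, 1.5])
    def test_bad_proportion(self, dwp):
        with pytest.raises(ValidationError):
            dry_to_wet(10.0, dwp)

    def test_negative_concentration(self):
        with pytest.raises(ValidationError):
            dry_to_wet(-1.0, 0.5)

    @given(
        a=st.floats(0, 1e6),
        b=st.floats(0, 1e6),
        p=st.floats(1e-6, 1.0),
    )
    def test_linearity(self, a, b, p):
        assert dry_to_wet(a + b, p) == pytest.approx(
            dry_to_wet(a, p) + dry_to_wet(b, p), rel=1e-12, abs=1e-12
        )


class TestCensorSpike:
    def test_below_dl_zero_substitution(self):
        assert censor_spike(0.8, 200.0) == (0.0, True)

    def test_above_dl_unchanged(self):
        assert censor_spike(5.0, 200.0) == (5.0, False)

    def test_half_dl(self):
        policy = DetectionPolicy(substitution=Substitution.HALF_DL)
        value, flagged = censor_spike(0.8, 200.0, policy)
        assert value == pytest.approx(0.5)
        assert flagged

    def test_flag_only(self):
        policy = DetectionPolicy(substitution=Substitution.FLAG_ONLY)
        assert censor_spike(0.8, 200.0, policy) == (0.8, True)

    def test_at_dl_not_censored(self):
        assert censor_spike(1.0, 200.0) == (1.0, False)

    def test_nonpositive_ambient_rejected(self):
        with pytest.raises(ValidationError):
            censor_spike(1.0, 0.0)

    @given(
        spike=st.floats(0, 1e3),
        ambient=st.floats(1e-6, 1e6),
        sub=st.sampled_from(list(Substitution)),
    )
    def test_idempotent(self, spike, ambient, sub):
        policy = DetectionPolicy(substitution=sub)
        once, _ = censor_spike(spike, ambient, policy)
        twice, _ = censor_spike(once, ambient, policy)
        assert twice == once

    def test_bad_dl_fraction(self):
        with pytest.raises(ValidationError):
            DetectionPolicy(spike_dl_fraction=1.5)


class TestOpenWaterMean:
    def test_simple_mean(self, calendar):
        samples = [make_sample(v, month=m) for v, m in [(1, 5), (2, 7), (3, 9)]]
        assert open_water_annual_mean(
            samples, 2005, calendar, IsotopeChannel.AMBIENT
        ) == pytest.approx(2.0)

    def test_out_of_window_excluded(self, calendar):
        samples = [make_sample(v, month=m) for v, m in [(1, 5), (2, 7)]]
        samples.append(make_sample(100.0, month=12))
        assert open_water_annual_mean(
            samples, 2005, calendar, IsotopeChannel.AMBIENT
        ) == pytest.approx(1.5)

    def test_empty_window_is_missing(self, calendar):
        samples = [make_sample(1.0, month=1)]
        assert open_water_annual_mean(samples, 2005, calendar, IsotopeChannel.AMBIENT) is None

    def test_other_year_excluded(self, calendar):
        samples = [make_sample(1.0, year=2004)]
        assert open_water_annual_mean(samples, 2005, calendar, IsotopeChannel.AMBIENT) is None

    def test_order_and_duplication_invariance(self, calendar):
        samples = [make_sample(v, month=m) for v, m in [(1, 5), (2, 7), (3, 9)]]
        base = open_water_annual_mean(samples, 2005, calendar, IsotopeChannel.AMBIENT)
        rev = open_water_annual_mean(samples[::-1], 2005, calendar, IsotopeChannel.AMBIENT)
        dup = open_water_annual_mean(samples * 3, 2005, calendar, IsotopeChannel.AMBIENT)
        assert base == rev == pytest.approx(dup)

    def test_depth_filter(self, calendar):
        shallow = make_sample(1.0, compartment=Compartment.WATER, depth_m=2.0)
        deep = make_sample(9.0, compartment=Compartment.WATER, depth_m=8.0)
        assert open_water_annual_mean(
            [shallow, deep], 2005, calendar, IsotopeChannel.AMBIENT, max_depth_m=4.0
        ) == pytest.approx(1.0)


class TestDomainTypes:
    def test_channels_enumerated(self):
        assert {c.value for c in IsotopeChannel} == {
            "ambient", "lake_spike", "upland_spike", "wetland_spike"
        }

    def test_water_requires_ng_per_l(self):
        with pytest.raises(ValidationError):
            CompartmentSample(
                compartment=Compartment.WATER,
                date=dt.date(2005, 6, 1),
                conc={IsotopeChannel.AMBIENT: 1.0},
                basis=Basis.WET,
                units=Units.NG_PER_G,
            )

    def test_sediment_must_be_dry(self):
        with pytest.raises(ValidationError):
            CompartmentSample(
                compartment=Compartment.SEDIMENT,
                date=dt.date(2005, 6, 1),
                conc={IsotopeChannel.AMBIENT: 1.0},
                basis=Basis.WET,
                units=Units.NG_PER_G,
            )

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            make_sample(-1.0)

    def test_fish_wet_basis_derivation(self):
        f = make_fish(dwp=0.25, conc_dw={IsotopeChannel.AMBIENT: 100.0})
        assert f.conc_ww(IsotopeChannel.AMBIENT) == pytest.approx(25.0)
        assert f.conc_ww(IsotopeChannel.LAKE_SPIKE) is None

    @pytest.mark.parametrize(
        "kwargs", [{"fl": 0.0}, {"mass": -5.0}, {"dwp": 0.0}, {"dwp": 1.2}]
    )
    def test_fish_invariants(self, kwargs):
        with pytest.raises(ValidationError):
            make_fish(**kwargs)

    def test_calendar_defaults(self, calendar):
        assert calendar.t0_year == 2007
        assert list(calendar.addition_years) == list(range(2001, 2008))
        assert list(calendar.recovery_years) == list(range(2008, 2016))
        assert calendar.open_water_months == frozenset(range(5, 11))

    def test_calendar_ordering_enforced(self):
        with pytest.raises(ValidationError):
            StudyCalendar(addition_start=2005, addition_end=2003, recovery_end=2010)


class TestCsvRoundTrip:
    def test_round_trip_bit_for_bit(self, tiny_dataset, tmp_path):
        d1 = tmp_path / "one"
        d2 = tmp_path / "two"
        write_dataset(tiny_dataset, d1)
        ds = read_dataset(d1)
        write_dataset(ds, d2)
        for name in ("samples.csv", "fish.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_round_trip_awkward_floats(self, tmp_path):
        fish = [
            make_fish(fl=475.00000000001, mass=1.0 / 3.0, dwp=0.1 + 0.2,
                      conc_dw={IsotopeChannel.AMBIENT: 1e-12, IsotopeChannel.LAKE_SPIKE: 9.87654321e4})
        ]
        write_dataset(Dataset(fish=fish), tmp_path)
        back = read_dataset(tmp_path).fish[0]
        assert back.fork_length_mm == fish[0].fork_length_mm
        assert back.mass_g == fish[0].mass_g
        assert back.dw_proportion == fish[0].dw_proportion
        assert back.conc_dw == fish[0].conc_dw

    def test_negative_mass_reported_with_row(self, tmp_path):
        write_dataset(Dataset(fish=[make_fish(), make_fish()]), tmp_path)
        text = (tmp_path / "fish.csv").read_text().splitlines()
        text[2] = text[2].replace("500.0", "-500.0")
        (tmp_path / "fish.csv").write_text("\n".join(text) + "\n")
        with pytest.raises(ValidationError) as err:
            read_dataset(tmp_path)
        assert err.value.rows == [2]

    def test_empty_file_with_header(self, tmp_path):
        write_dataset(Dataset(), tmp_path)
        ds = read_dataset(tmp_path)
        assert ds.samples == [] and ds.fish == []

    def test_missing_column_is_schema_error(self, tmp_path, tiny_dataset):
        write_dataset(tiny_dataset, tmp_path)
        lines = (tmp_path / "samples.csv").read_text().splitlines()
        header = lines[0].replace("basis,", "")
        rows = [",".join(v for i, v in enumerate(r.split(",")) if i != 3) for r in lines[1:]]
        (tmp_path / "samples.csv").write_text("\n".join([header] + rows) + "\n")
        with pytest.raises(SchemaError):
            read_dataset(tmp_path)

    def test_missing_directory(self, tmp_path):
        with pytest.raises(SchemaError):
            read_dataset(tmp_path / "nope")

    def test_fish_ids_survive(self, tmp_path):
        fish = [make_fish(fish_id="np00001", age_class="adult", age_years=4)]
        write_dataset(Dataset(fish=fish), tmp_path)
        back = read_dataset(tmp_path).fish[0]
        assert back.fish_id == "np00001"
        assert back.age_years == 4
        assert back.age_class.value == "adult"
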