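import math

import pytest

from biometeokit.errors import DomainError, UsageError
from biometeokit.radiation import (
    SIGMA,
    RadiationConfig,
    SiteTime,
    actual_fluxes,
    atmospheric_emissivity,
    clear_sky_fluxes,
    solar_position,
    surface_and_longwave,
    tmrt_calc,
    tmrt_compose,
)


class TestSiteTime:
    def test_bounds(self):
        with pytest.raises(DomainError):
            SiteTime(longitude=200.0, latitude=0.0, day_of_year=1,
                     hour_of_day=0.0, timezone_offset=0.0)
        with pytest.raises(DomainError):
            SiteTime(longitude=0.0, latitude=95.0, day_of_year=1,
                     hour_of_day=0.0, timezone_offset=0.0)
        with pytest.raises(DomainError):
            SiteTime(longitude=0.0, latitude=0.0, day_of_year=370,
                     hour_of_day=0.0, timezone_offset=0.0)

    def test_now_default_fills_fields(self):
        site = SiteTime(longitude=0.0, latitude=0.0)
        assert 1 <= site.day_of_year <= 366
        assert 0.0 <= site.hour_of_day < 24.0

    def test_fractional_hours_accepted(self):
        site = SiteTime(longitude=121.5, latitude=23.5, day_of_year=210,
                        hour_of_day=15.8, timezone_offset=8.0)
        assert site.hour_of_day == 15.8


class TestSolarPosition:
    def test_equator_equinox_noon_overhead(self):
        site = SiteTime(longitude=0.0, latitude=0.0, day_of_year=80,
                        hour_of_day=12.0, timezone_offset=0.0)
        zen, _az, _esf = solar_position(site)
        assert zen < 2.0

    def test_tropic_solstice_noon_overhead(self):
        site = SiteTime(longitude=0.0, latitude=23.45, day_of_year=172,
                        hour_of_day=12.0, timezone_offset=0.0)
        zen, _az, _esf = solar_position(site)
        assert zen < 1.0

    def test_against_frozen_astronomical_oracle(self, solar_oracle):
        worst = 0.0
        for row in solar_oracle:
            site = SiteTime(
                longitude=row["lon"], latitude=row["lat"],
                sea_level_height=row["elev"], day_of_year=row["doy"],
                hour_of_day=row["hour"], timezone_offset=row["tz"],
            )
            zen, _az, _ = solar_position(site)
            worst = max(worst, abs(zen - row["zenith"]))
        assert worst < 0.5

    def test_earth_sun_factor_seasonal(self):
        jan = solar_position(SiteTime(longitude=0, latitude=0, day_of_year=3,
                                      hour_of_day=12.0, timezone_offset=0.0))[2]
        jul = solar_position(SiteTime(longitude=0, latitude=0, day_of_year=185,
                                      hour_of_day=12.0, timezone_offset=0.0))[2]
        assert jan > 1.0 > jul  # perihelion in early January


class TestClearSkyFluxes:
    def test_night_is_zero(self):
        assert clear_sky_fluxes(120.0, 1.0) == (0.0, 0.0, 0.0)

    def test_no_atmosphere_limit(self):
        imax, _g, _d = clear_sky_fluxes(0.0, 1.0, ltf=1e-9, VP=10.0)
        assert imax == pytest.approx(1367.0, rel=1e-3)

    def test_bracket_at_thirty_degrees(self):
        imax, gmax, dmax = clear_sky_fluxes(30.0, 1.0, 0.0, 3.0, 12.0)
        assert 700.0 <= gmax <= 1000.0
        assert 0.05 <= dmax / gmax <= 0.35
        assert gmax == pytest.approx(imax * math.cos(math.radians(30.0)) + dmax)

    def test_elevation_increases_beam(self):
        low = clear_sky_fluxes(40.0, 1.0, 0.0, 3.0)[0]
        high = clear_sky_fluxes(40.0, 1.0, 2000.0, 3.0)[0]
        assert high > low


class TestActualFluxes:
    # self-consistent clear-sky triple: Gmax = Imax*cos(30 deg) + Dmax
    CLEAR = (900.0, 900.0 * math.cos(math.radians(30.0)) + 70.0, 70.0)

    def test_overcast_kasten_czeplak(self):
        _i, gtat, _d = actual_fluxes(self.CLEAR, N=8.0, zenith=30.0)
        assert gtat == pytest.approx(self.CLEAR[1] * (1.0 - 0.75), rel=1e-9)

    def test_clear_is_identity(self):
        itat, gtat, dtat = actual_fluxes(self.CLEAR, N=0.0, zenith=30.0)
        assert (itat, gtat, dtat) == pytest.approx(self.CLEAR, abs=1e-9)

    def test_cloud_law_exact_for_all_octas(self):
        for n in range(9):
            _i, gtat, _d = actual_fluxes(self.CLEAR, N=float(n), zenith=30.0)
            expected = self.CLEAR[1] * (1.0 - 0.75 * (n / 8.0) ** 3.4)
            assert gtat == pytest.approx(expected, rel=1e-9)

    def test_fog_forces_full_diffuse(self):
        itat, gtat, dtat = actual_fluxes(
            self.CLEAR, N=0.0, RH=95.0, foglimit=90.0, zenith=30.0,
            G_override=200.0,
        )
        assert itat == 0.0
        assert dtat == gtat == 200.0

    def test_negative_override_rejected(self):
        with pytest.raises(DomainError):
            actual_fluxes(self.CLEAR, G_override=-5.0, zenith=30.0)

    def test_sensor_spike_warns_but_keeps_value(self):
        with pytest.warns(UserWarning, match="spike"):
            _i, gtat, _d = actual_fluxes(self.CLEAR, G_override=1200.0, zenith=30.0)
        assert gtat == 1200.0

    def test_decomposition_invariant(self):
        for n in (0.0, 2.0, 5.0, 8.0):
            itat, gtat, dtat = actual_fluxes(self.CLEAR, N=n, zenith=30.0)
            assert gtat == pytest.approx(
                itat * math.cos(math.radians(30.0)) + dtat, abs=0.5
            )

    def test_dgratio_split(self):
        itat, gtat, dtat = actual_fluxes(
            self.CLEAR, G_override=500.0, DGratio=0.4, zenith=30.0
        )
        assert dtat == pytest.approx(200.0)
        assert gtat == pytest.approx(500.0)
        assert itat == pytest.approx(300.0 / math.cos(math.radians(30.0)))


class TestSurfaceAndLongwave:
    def test_night_override_stefan_boltzmann(self):
        a, eu, _es, tob = surface_and_longwave(10.0, 8.0, Gtat=0.0,
                                               Tob_override=10.0)
        assert tob == 10.0
        assert eu == pytest.approx(0.97 * SIGMA * 283.15**4, rel=1e-12)

    def test_cloud_increases_atmospheric_longwave(self):
        a0 = surface_and_longwave(20.0, 11.7, N=0.0)[0]
        a8 = surface_and_longwave(20.0, 11.7, N=8.0)[0]
        assert a8 > a0

    def test_clear_sky_bracket(self):
        a, *_ = surface_and_longwave(20.0, 11.7, N=0.0)
        assert 280.0 <= a <= 360.0

    def test_emissivity_capped(self):
        assert atmospheric_emissivity(45.0, 8.0) <= 1.0

    def test_daytime_surface_warmer_than_air(self):
        *_, tob = surface_and_longwave(25.0, 15.0, Gtat=700.0, zenith=30.0)
        assert tob > 25.0


class TestTmrtCompose:
    def test_blackbody_enclosure_identity(self):
        t = 20.0
        f = SIGMA * (t + 273.15) ** 4
        tmrt = tmrt_compose(0.0, 0.0, 0.0, f, f, f, zenith=120.0)
        assert tmrt == pytest.approx(t, abs=1e-6)

    def test_shortwave_raises_tmrt(self):
        t = 20.0
        f = SIGMA * (t + 273.15) ** 4
        base = tmrt_compose(0.0, 0.0, 0.0, f, f, f, zenith=120.0)
        sunny = tmrt_compose(600.0, 80.0, 600.0, f, f, f, zenith=40.0)
        assert sunny > base

    def test_equal_longwave_reduction(self):
        f = 400.0
        tmrt = tmrt_compose(0.0, 0.0, 0.0, f, f, f, zenith=120.0)
        assert tmrt == pytest.approx((f / SIGMA) ** 0.25 - 273.15, abs=1e-9)

    def test_monotone_in_each_flux(self):
        t = 15.0
        f = SIGMA * (t + 273.15) ** 4
        base = tmrt_compose(100.0, 50.0, 150.0, f, f, f, zenith=45.0)
        for bump in ("Itat", "Dtat", "A", "Eu", "Es"):
            args = dict(Itat=100.0, Dtat=50.0, Gtat=150.0, A=f, Eu=f, Es=f)
            args[bump] = args[bump] + 50.0
            up = tmrt_compose(args["Itat"], args["Dtat"], args["Gtat"],
                              args["A"], args["Eu"], args["Es"], zenith=45.0)
            assert up >= base

    def test_negative_flux_rejected(self):
        with pytest.raises(DomainError):
            tmrt_compose(-1.0, 0.0, 0.0, 300.0, 300.0, 300.0)


class TestTmrtCalc:
    def test_paper_call_defaults(self):
        b = tmrt_calc(Ta=20.0, RH=50.0, v=0.1, longitude=121.5, latitude=23.5,
                      sea_level_height=30.0)
        for name, val in b.as_dict().items():
            assert math.isfinite(val), name
        for name in ("Imax", "Gmax", "Dmax", "Itat", "Gtat", "Dtat", "A",
                     "Eu", "Es"):
            assert getattr(b, name) >= 0.0

    def test_paper_call_cloudy_attenuates(self):
        b = tmrt_calc(Ta=20.0, RH=50.0, v=0.1, longitude=121.5, latitude=23.5,
                      sea_level_height=30.0, hour_of_day=15.8, day_of_year=210,
                      timezone_offset=8.0, config=RadiationConfig(N=6.0))
        assert b.Gtat < b.Gmax
        assert b.Itat <= b.Imax

    def test_midnight_longwave_only(self):
        b = tmrt_calc(Ta=15.0, RH=60.0, v=1.0, longitude=10.0, latitude=48.0,
                      sea_level_height=200.0, hour_of_day=0.0, day_of_year=180,
                      timezone_offset=1.0)
        assert b.Itat == b.Gtat == b.Dtat == 0.0
        assert b.Tmrt <= 15.0 + 1.0

    def test_day_night_consistency(self):
        site = dict(longitude=10.0, latitude=48.0, sea_level_height=0.0,
                    day_of_year=172, timezone_offset=1.0)
        for hour in (0.0, 2.0, 22.5, 23.9):
            b = tmrt_calc(Ta=12.0, RH=70.0, v=1.0, hour_of_day=hour, **site)
            assert b.Imax == b.Itat == 0.0

    def test_sky_view_reduction_at_clear_noon(self):
        kwargs = dict(Ta=25.0, RH=40.0, v=1.0, longitude=0.0, latitude=45.0,
                      sea_level_height=0.0, hour_of_day=12.0, day_of_year=172,
                      timezone_offset=0.0)
        full = tmrt_calc(**kwargs)
        half = tmrt_calc(**kwargs, config=RadiationConfig(OmegaF=0.5))
        assert half.Tmrt < full.Tmrt

    def test_decomposition_holds(self):
        b = tmrt_calc(Ta=22.0, RH=55.0, v=1.0, longitude=0.0, latitude=45.0,
                      sea_level_height=0.0, hour_of_day=14.5, day_of_year=200,
                      timezone_offset=0.0, config=RadiationConfig(N=3.0))
        site = SiteTime(longitude=0.0, latitude=45.0, sea_level_height=0.0,
                        day_of_year=200, hour_of_day=14.5, timezone_offset=0.0)
        zen, _a, _e = solar_position(site)
        assert b.Gtat == pytest.approx(
            b.Itat * math.cos(math.radians(zen)) + b.Dtat, abs=0.5
        )

    def test_missing_coordinates_usage_error(self):
        with pytest.raises(UsageError):
            tmrt_calc(Ta=20.0, RH=50.0, v=0.1)

    def test_needs_humidity(self):
        with pytest.raises(UsageError):
            tmrt_calc(Ta=20.0, v=0.1, longitude=0.0, latitude=0.0)

    def test_inconsistent_humidity_pair(self):
        with pytest.raises(UsageError):
            tmrt_calc(Ta=20.0, VP=11.69, RH=80.0, v=0.1,
                      longitude=0.0, latitude=0.0)

    def test_sunlit_tmrt_exceeds_air(self):
        b = tmrt_calc(Ta=25.0, RH=40.0, v=1.0, longitude=0.0, latitude=45.0,
                      sea_level_height=0.0, hour_of_day=12.0, day_of_year=172,
                      timezone_offset=0.0)
        assert b.Tmrt > 25.0 + 10.0


class TestRadiationConfig:
    def test_defaults(self):
        c = RadiationConfig()
        assert (c.N, c.OmegaF, c.alb, c.albhum) == (0.0, 1.0, 0.3, 0.3)
        assert c.RedGChk is False
        assert c.foglimit == 90.0
        assert c.bowen == 1.0

    @pytest.mark.parametrize(
        "kwargs", [dict(N=9.0), dict(OmegaF=1.5), dict(alb=-0.1), dict(ltf=0.0)]
    )
    def test_validation(self, kwargs):
        with pytest.raises(DomainError):
            RadiationConfig(**kwargs)
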