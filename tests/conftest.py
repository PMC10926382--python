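import textwrap

import pytest


@pytest.fixture
def sim_config(tmp_path):
    """A two-station planar simulation config on disk."""
    path = tmp_path / "scenario.ini"
    path.write_text(
        textwrap.dedent(
            """\
            [model]
            t_nest = 45
            s_min = 1.8
            s_max = 5.4

            [simulation]
            nest_x_m = 0
            nest_y_m = 400
            stations = BS1:0:0, BS2:300:150
            n_hornets_per_station = 1
            trips_per_hornet = 4
            speed_mean = 2.7
            speed_sd = 0.5
            handling_mean = 45
            handling_sd = 10
            bearing_noise_sd = 3
            seed = 7
            """
        )
    )
    return path


@pytest.fixture
def noise_free_config(tmp_path):
    path = tmp_path / "noise_free.ini"
    path.write_text(
        "[simulation]\n"
        "nest_x_m = 0\nnest_y_m = 400\n"
        "stations = BS1:0:0, BS2:300:150\n"
        "n_hornets_per_station = 1\ntrips_per_hornet = 3\n"
        "speed_mean = 2.7\nspeed_sd = 0\n"
        "handling_mean = 45\nhandling_sd = 0\n"
        "bearing_noise_sd = 0\nseed = 3\n"
    )
    return path
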