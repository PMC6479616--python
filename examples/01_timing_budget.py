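"""Per-line timing budget of a line-scan imager: transfer time, line rate,
efficiency, and recovery of the constant overhead from a timing log.

A scan line costs exposure plus overhead (network transfer, API calls,
buffer copies, actuator motion) plus random OS delays; the efficiency
T_exp / T_line says how much wall time actually collects photons.
"""

from mirrorscan import (
    DelayModel, efficiency, fit_extra_delay, image_time, lps, simulate_timing,
    transfer_time,
)

# network transfer of one full 2048 x 1088 frame over Gigabit Ethernet
for bits in (8, 12):
    t_rx = transfer_time(2048, 1088, bits, 1e9, omega=1.019)
    print(f"{bits:>2}-bit frame transfer: {t_rx * 1e3:6.2f} ms "
          f"(caps the line rate at {1 / t_rx:5.2f} lines/s)")

# a realistic overhead budget and its effect on line rate and efficiency
dm = DelayModel(t_exp=0.1, t_rx=0.0182, t_api=0.012, t_mcpy=0.002, t_act=0.0011)
print(f"\noverhead t_extra = {dm.t_extra * 1e3:.1f} ms")
for t_exp in (0.01, 0.1, 0.5):
    print(f"  t_exp = {t_exp * 1e3:4.0f} ms -> {lps(t_exp, dm.t_extra):6.2f} lines/s, "
          f"efficiency {efficiency(t_exp, dm.t_extra):.2f}")

# recover the overhead from a (simulated) timing log with random OS delays
noisy = DelayModel(t_rx=0.0182, t_api=0.012, t_mcpy=0.002, t_act=0.0011,
                   t_rand_sigma=0.005, t_rand_law="exponential")
log = simulate_timing(noisy, [0.01, 0.05, 0.1, 0.2, 0.5], 50, seed=1)
fit = fit_extra_delay(log)
print(f"\nfitted t_extra from {fit.n_records} log lines: "
      f"{fit.t_extra_s * 1e3:.1f} ms (generator used {noisy.t_extra * 1e3:.1f} ms "
      f"plus 5 ms mean OS delay)")

# total image time for a 1200-line scan at 75% average efficiency
print(f"\n1200-line image at t_line = 133 ms, eps = 0.75: "
      f"{image_time(1200, 0.1333, 0.75):.0f} s")
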