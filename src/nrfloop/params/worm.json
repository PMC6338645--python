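{
  "k_mA": 5.4537048800707115,
  "d_mA": 5.281886713069244,
  "k_A": 5.405143163863799,
  "e_A": 0.027336798226206802,
  "d_A": 5.405143163863799,
  "k_p0": 0.28190779270586275,
  "k_p": 0.02485753756799117,
  "k_dp": 1.0,
  "k_mN": 1.2,
  "c_N": 0.9401105463199172,
  "d_mN": 2.2620794706388034,
  "k_N": 1.0,
  "k_N0": 0.048211025093208584,
  "k_N1": 0.005909019395430695,
  "k_N2": 0.00045305145533526054,
  "d_N": 3.16192066979414,
  "K_N": 0.01452609185055547,
  "h": 5.854676316686629,
  "k_U0": 3.3690635701165656e-05,
  "k_U": 4.4883921864934315,
  "U_T": 1.0,
  "d_U": 6.643892918972767,
  "k_L": 1.0,
  "g_L": 0.6663130938375234,
  "d_L": 1.6832383925996652,
  "k_P": 1.0,
  "b_P": 0.5,
  "d_P0": 0.2,
  "d_P1": 0.5
}
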