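{
  "k_mA": 15.008255480468787,
  "d_mA": 2.1440364966629497,
  "k_A": 1.8748692789119454,
  "e_A": 6.9588182187957734,
  "d_A": 1.8748692789119454,
  "k_p0": 0.4877162468803284,
  "k_p": 0.38658183734260265,
  "k_dp": 0.5205771174683357,
  "k_mN": 1.2,
  "c_N": 0.9401105463199172,
  "d_mN": 2.2620794706388034,
  "k_N": 1.0,
  "k_N0": 0.048211025093208584,
  "k_N1": 0.003714686908991074,
  "k_N2": 7.084857186575452,
  "d_N": 1.9449739071403347,
  "K_N": 0.2503835721885633,
  "h": 5.854676316686629,
  "k_U0": 0.00012354087685377354,
  "k_U": 0.23115545395243098,
  "U_T": 1.0,
  "d_U": 6.643892918972767,
  "k_L": 1.0,
  "g_L": 0.0,
  "d_L": 6.595569622139436,
  "k_P": 1.0,
  "b_P": 0.5,
  "d_P0": 0.2,
  "d_P1": 0.5
}
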