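1H NMR (600 MHz, DMSO-d6) Shift 10.86 (s, 1H), 7.45 (d, J = 7.8 Hz, 1H), 7.31 (d, J = 8.0 Hz, 1H), 7.26 (t, J = 7.8 Hz, 1H), 7.08 (dd, J = 8.0, 7.5 Hz, 1H), 7.00 (dd, J = 7.8, 7.5 Hz, 1H), 6.86 (dd, J = 8.2, 2.4 Hz, 1H), 6.84 (d, J = 7.8 Hz, 1H), 6.75 (br d, J = 2.3 Hz, 1H), 4.98 (s, 1H), 4.48 (dt, J = 47.5, 6.6 Hz, 2H), 3.95 (t, J = 5.6 Hz, 2H), 3.57 (qd, J = 13.0, 9.3 Hz, 1H), 3.12 (dqd, J = 11.0, 6.8, 5.0 Hz, 1H), 3.01 (qd, J = 18.0, 9.3 Hz, 1H), 2.83 (t, J = 5.7 Hz, 2H), 2.64 (dd, J = 15.8, 5.0 Hz, 1H), 2.57 (dd, J = 15.8, 11.0 Hz, 1H), 2.62 (t, J = 6.6 Hz, 2H), 1.76 (dquin, J = 26.1, 6.6 Hz, 2H), 1.11 (d, J = 6.8 Hz, 3H)
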