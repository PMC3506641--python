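[directions = 65]

CoordinateSystem = xyz

Normalisation = none

Vector[0] = (0, 0, 0)

Vector[1] = (0, 0, 0)

Vector[2] = (0, 0, 0)

Vector[3] = (0, 0, 0)

Vector[4] = (0, 0, 0)

Vector[5] = (1.00000, 0.00000, 0.00000)

Vector[6] = (0.16600, 0.98600, 0.00000)

Vector[7] = (0.11000, −0.66400, −0.74000)

Vector[8] = (0.90100, −0.41900, −0.11000)

Vector[9] = (0.16900, 0.60100, −0.78100)

Vector[10] = (0.81500, 0.38600, −0.43300)

Vector[11] = (−0.65600, −0.36600, −0.66000)

Vector[12] = (−0.58200, −0.80000, −0.14300)

Vector[13] = (−0.90000, −0.25900, −0.35000)

Vector[14] = (−0.69300, 0.69800, -0.17800)

Vector[15] = (0.35700, −0.92400, −0.14000)

Vector[16] = (0.54300, −0.48800, −0.68300)

Vector[17] = (0.52500, 0.39600, −0.75300)

Vector[18] = (0.63900, −0.68900, −0.34100)

Vector[19] = (−0.33000, −0.01300, −0.94400)

Vector[20] = (0.52400, 0.78300, −0.33500)

Vector[21] = (0.60900, −0.06500, −0.79100)

Vector[22] = (0.22000, −0.23300, −0.94700)

Vector[23] = (−0.00400, −0.91000, −0.41500)

Vector[24] = (−0.51100, 0.62700, −0.58900)

Vector[25] = (−0.41400, −0.73700, −0.53500)

Vector[26] = (−0.67900, 0.13900, −0.72100)

Vector[27] = (−0.88400, 0.29600, −0.36200)

Vector[28] = (−0.26200, −0.43200, −0.86300)

Vector[29] = (0.08800, 0.18500, −0.97900)

Vector[30] = (−0.29400, 0.90700, −0.30200)

Vector[31] = (0.88700, −0.08900, −0.45300)

Vector[32] = (−0.25700, 0.44300, −0.85900)

Vector[33] = (0.08600, 0.86700, −0.49100)

Vector[34] = (0.86300, 0.50400, −0.02500)

Vector[35] = (−1.00000, −1.00000, −1.00000)

Vector[36] = (1.00000, −1.00000, −1.00000)

Vector[37] = (−1.00000, 1.00000, −1.00000)

Vector[38] = (1.00000, 1.00000, −1.00000)

Vector[39] = (1.00000, 1.00000, 0.00000)

Vector[40] = (−0.00000, −1.00000, −1.00000)

Vector[41] = (−1.00000, −0.00000, −1.00000)

Vector[42] = (−1.00000, 1.00000, 0.00000)

Vector[43] = (−0.00000, 1.00000, −1.00000)

Vector[44] = (1.00000, −0.00000, −1.00000)

Vector[45] = (1.00000, −0.11968, −0.22826)

Vector[46] = (0.45391, 1.00000, −0.74490)

Vector[47] = (0.30929, −0.52908, −1.00000)

Vector[48] = (1.00000, 0.32570, −0.82547)

Vector[49] = (−0.53649, −0.28378, −1.00000)

Vector[50] = (1.00000, 0.28277, −0.16662)

Vector[51] = (0.37769, 0.13072, −1.00000)

Vector[52] = (−0.18512, 0.21731, −1.00000)

Vector[53] = (−0.32054, −1.00000, −0.32795)

Vector[54] = (0.37433, 1.00000, −0.18999)

Vector[55] = (−1.00000, 0.49160, −0.79472)

Vector[56] = (−0.09712, 1.00000, −0.03398)

Vector[57] = (−1.00000, −0.00905, −0.41514)

Vector[58] = (0.36282, −1.00000, −0.54229)

Vector[59] = (−0.52123, 1.00000, −0.11772)

Vector[60] = (−0.31196, 1.00000, −0.73018)

Vector[61] = (−1.00000, −0.69636, −0.40808)

Vector[62] = (−1.00000, 0.32257, −0.12697)

Vector[63] = (1.00000, −0.48206, −0.55084)

Vector[64] = (−0.06116, −0.17609, −1.00000)
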