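measure,band,contrast,median,ci_low,ci_high,rope_low,rope_high
T,delta,Stim01 - Pre,0.0013,-0.0048,0.0072,-0.0127,0.0173
T,delta,Stim02 - Pre,0.0039,-0.0026,0.0102,-0.0127,0.0173
T,delta,Stim03 - Pre,0.0026,-0.0037,0.0088,-0.0127,0.0173
T,delta,Stim04 - Pre,0.0084,0.0021,0.0149,-0.0127,0.0173
T,delta,Stim05 - Pre,0.0039,0.0026,0.0104,-0.0127,0.0173
T,theta,Stim01 - Pre,-0.0027,-0.0083,0.0031,-0.0108,0.0183
T,theta,Stim02 - Pre,0.0016,-0.0039,0.0067,-0.0108,0.0183
T,theta,Stim03 - Pre,0.0006,-0.0048,0.0059,-0.0108,0.0183
T,theta,Stim04 - Pre,0.0059,0.0004,0.0114,-0.0108,0.0183
T,theta,Stim05 - Pre,0.0016,-0.0044,0.0071,-0.0108,0.0183
T,alpha,Stim01 - Pre,-0.0016,-0.0087,0.0049,-0.0210,0.00691
T,alpha,Stim02 - Pre,-0.0020,-0.0106,0.0067,-0.0210,0.00691
T,alpha,Stim03 - Pre,-0.0102,-0.0168,-0.0033,-0.0210,0.00691
T,alpha,Stim04 - Pre,-0.0114,-0.0180,-0.0043,-0.0210,0.00691
T,alpha,Stim05 - Pre,-0.0039,-0.0119,0.0038,-0.0210,0.00691
T,beta,Stim01 - Pre,-0.0003,-0.0036,0.0033,-0.01,0.01
T,beta,Stim02 - Pre,0.0008,-0.0017,0.0035,-0.01,0.01
T,beta,Stim03 - Pre,-0.0004,-0.0030,0.0023,-0.01,0.01
T,beta,Stim04 - Pre,0.0009,-0.0016,0.0032,-0.01,0.01
T,beta,Stim05 - Pre,0.0008,-0.0017,0.0032,-0.01,0.01
T,gamma,Stim01 - Pre,0.0026,0.0010,0.0043,0.00,0.01
T,gamma,Stim02 - Pre,0.0020,0.0002,0.0040,0.00,0.01
T,gamma,Stim03 - Pre,0.0024,0.0006,0.0041,0.00,0.01
T,gamma,Stim04 - Pre,0.0039,0.0023,0.0055,0.00,0.01
T,gamma,Stim05 - Pre,0.0026,0.0010,0.0044,0.00,0.01
E,delta,Stim01 - Pre,0.0006,-0.0040,0.0028,-0.0080,0.0104
E,delta,Stim02 - Pre,0.0009,-0.0027,0.0047,-0.0080,0.0104
E,delta,Stim03 - Pre,0,-0.0035,0.0036,-0.0080,0.0104
E,delta,Stim04 - Pre,0.0038,0.0002,0.0037,-0.0080,0.0104
E,delta,Stim05 - Pre,0.0014,-0.0022,0.0051,-0.0080,0.0104
E,theta,Stim01 - Pre,-0.0021,-0.0052,0.0007,-0.0066,0.0100
E,theta,Stim02 - Pre,0.0002,-0.0025,0.0032,-0.0066,0.0100
E,theta,Stim03 - Pre,-0.0002,-0.0030,0.0026,-0.0066,0.0100
E,theta,Stim04 - Pre,0.0026,-0.0023,0.0055,-0.0066,0.0100
E,theta,Stim05 - Pre,0.0008,0.0021,0.0040,-0.0066,0.0100
E,alpha,Stim01 - Pre,-0.0019,-0.0052,0.0015,-0.0129,0.0075
E,alpha,Stim02 - Pre,-0.0010,-0.0055,0.0039,-0.0129,0.0075
E,alpha,Stim03 - Pre,-0.0058,-0.0093,0.0024,-0.0129,0.0075
E,alpha,Stim04 - Pre,-0.0060,-0.0094,0.0025,-0.0129,0.0075
E,alpha,Stim05 - Pre,0.0021,-0.0062,0.0019,-0.0129,0.0075
E,beta,Stim01 - Pre,-0.0003,-0.0022,0.0016,-0.0049,0.0040
E,beta,Stim02 - Pre,0.0004,-0.0010,0.0019,-0.0049,0.0040
E,beta,Stim03 - Pre,-0.0002,-0.0016,0.0013,-0.0049,0.0040
E,beta,Stim04 - Pre,0.0006,-0.0008,0.0019,-0.0049,0.0040
E,beta,Stim05 - Pre,0.0005,-0.0008,0.0018,-0.0049,0.0040
E,gamma,Stim01 - Pre,0.0012,0.0003,0.0021,-0.0005,0.0043
E,gamma,Stim02 - Pre,0.0010,0,0.0019,-0.0005,0.0043
E,gamma,Stim03 - Pre,0.0011,0.0001,0.0020,-0.0005,0.0043
E,gamma,Stim04 - Pre,0.0020,0.0011,0.0029,-0.0005,0.0043
E,gamma,Stim05 - Pre,0.0014,0.0004,0.0023,-0.0005,0.0043
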