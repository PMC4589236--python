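genotype,auto_male_pct,auto_n,manual_male_pct,manual_n
wild-type,0.23,28185,0.35,4790
brc-1,7.86,4428,6.35,3463
C30G12.6,1.59,5297,2.30,4351
cep-1,3.20,5712,4.59,4050
cki-2,0.23,3532,0.44,3407
coh-3,0.99,3130,1.58,1893
F52H3.4,0.11,1842,0.20,3422
fbf-2,0.47,4478,0.15,4121
fox-1,0.38,6386,0.29,3424
gpr-2,0.43,5778,0.30,4047
hcp-2,0.20,2492,0.58,1560
her-1,0.42,5457,1.63,2767
him-3,13.54,3663,16.05,1676
him-5,36.46,3999,36.04,2486
him-8,30.08,8113,31.09,1933
klp-10,0.21,3286,0.11,4596
sdc-1,0.49,3447,0.13,2267
sel-10,0.23,4686,0.05,2040
set-2,0.14,4239,0.00,2014
sgo-1,0.22,5960,0.25,4463
skr-1,0.71,3815,3.00,3436
smk-1,0.27,3377,2.24,1382
srgp-1,0.24,2519,0.10,3109
sur-7,0.49,2859,0.38,1572
T08D2.7,0.42,6174,0.27,4085
unc-86,2.42,5985,3.16,1394
W02D9.3,0.43,3038,0.26,4959
zhp-3,0.10,4154,0.11,4737
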