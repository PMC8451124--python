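alpha2	name	african
AD	Andorra	0
AE	United Arab Emirates	0
AF	Afghanistan	0
AG	Antigua and Barbuda	0
AL	Albania	0
AM	Armenia	0
AO	Angola	1
AR	Argentina	0
AT	Austria	0
AU	Australia	0
AZ	Azerbaijan	0
BA	Bosnia and Herzegovina	0
BB	Barbados	0
BD	Bangladesh	0
BE	Belgium	0
BF	Burkina Faso	1
BG	Bulgaria	0
BH	Bahrain	0
BI	Burundi	1
BJ	Benin	1
BN	Brunei	0
BO	Bolivia	0
BR	Brazil	0
BS	Bahamas	0
BT	Bhutan	0
BW	Botswana	1
BY	Belarus	0
BZ	Belize	0
CA	Canada	0
CD	Democratic Republic of the Congo	1
CF	Central African Republic	1
CG	Congo	1
CH	Switzerland	0
CI	Cote d'Ivoire	1
CL	Chile	0
CM	Cameroon	1
CN	China	0
CO	Colombia	0
CR	Costa Rica	0
CU	Cuba	0
CV	Cabo Verde	1
CY	Cyprus	0
CZ	Czechia	0
DE	Germany	0
DJ	Djibouti	1
DK	Denmark	0
DM	Dominica	0
DO	Dominican Republic	0
DZ	Algeria	1
EC	Ecuador	0
EE	Estonia	0
EG	Egypt	1
EH	Western Sahara	1
ER	Eritrea	1
ES	Spain	0
ET	Ethiopia	1
FI	Finland	0
FJ	Fiji	0
FR	France	0
GA	Gabon	1
GB	United Kingdom	0
GD	Grenada	0
GE	Georgia	0
GH	Ghana	1
GM	Gambia	1
GN	Guinea	1
GQ	Equatorial Guinea	1
GR	Greece	0
GT	Guatemala	0
GW	Guinea-Bissau	1
GY	Guyana	0
HK	Hong Kong	0
HN	Honduras	0
HR	Croatia	0
HT	Haiti	0
HU	Hungary	0
ID	Indonesia	0
IE	Ireland	0
IL	Israel	0
IN	India	0
IQ	Iraq	0
IR	Iran	0
IS	Iceland	0
IT	Italy	0
JM	Jamaica	0
JO	Jordan	0
JP	Japan	0
KE	Kenya	1
KG	Kyrgyzstan	0
KH	Cambodia	0
KM	Comoros	1
KP	North Korea	0
KR	South Korea	0
KW	Kuwait	0
KZ	Kazakhstan	0
LA	Laos	0
LB	Lebanon	0
LC	Saint Lucia	0
LI	Liechtenstein	0
LK	Sri Lanka	0
LR	Liberia	1
LS	Lesotho	1
LT	Lithuania	0
LU	Luxembourg	0
LV	Latvia	0
LY	Libya	1
MA	Morocco	1
MC	Monaco	0
MD	Moldova	0
ME	Montenegro	0
MG	Madagascar	1
MK	North Macedonia	0
ML	Mali	1
MM	Myanmar	0
MN	Mongolia	0
MO	Macao	0
MR	Mauritania	1
MT	Malta	0
MU	Mauritius	1
MV	Maldives	0
MW	Malawi	1
MX	Mexico	0
MY	Malaysia	0
MZ	Mozambique	1
NA	Namibia	1
NE	Niger	1
NG	Nigeria	1
NI	Nicaragua	0
NL	Netherlands	0
NO	Norway	0
NP	Nepal	0
NZ	New Zealand	0
OM	Oman	0
PA	Panama	0
PE	Peru	0
PG	Papua New Guinea	0
PH	Philippines	0
PK	Pakistan	0
PL	Poland	0
PR	Puerto Rico	0
PS	Palestine	0
PT	Portugal	0
PY	Paraguay	0
QA	Qatar	0
RE	Reunion	1
RO	Romania	0
RS	Serbia	0
RU	Russia	0
RW	Rwanda	1
SA	Saudi Arabia	0
SC	Seychelles	1
SD	Sudan	1
SE	Sweden	0
SG	Singapore	0
SH	Saint Helena	1
SI	Slovenia	0
SK	Slovakia	0
SL	Sierra Leone	1
SM	San Marino	0
SN	Senegal	1
SO	Somalia	1
SR	Suriname	0
SS	South Sudan	1
ST	Sao Tome and Principe	1
SV	El Salvador	0
SY	Syria	0
SZ	Eswatini	1
TD	Chad	1
TG	Togo	1
TH	Thailand	0
TJ	Tajikistan	0
TL	Timor-Leste	0
TM	Turkmenistan	0
TN	Tunisia	1
TO	Tonga	0
TR	Turkey	0
TT	Trinidad and Tobago	0
TW	Taiwan	0
TZ	Tanzania	1
UA	Ukraine	0
UG	Uganda	1
US	United States	0
UY	Uruguay	0
UZ	Uzbekistan	0
VC	Saint Vincent and the Grenadines	0
VE	Venezuela	0
VN	Vietnam	0
WS	Samoa	0
YE	Yemen	0
YT	Mayotte	1
ZA	South Africa	1
ZM	Zambia	1
ZW	Zimbabwe	1
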