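id,arm,time,event
C001,Cefixime,0.5,AF
C002,Cefixime,0.5,AF
C003,Cefixime,0.5,AF
C004,Cefixime,0.5,AF
C005,Cefixime,0.5,AF
C006,Cefixime,0.5,AF
C007,Cefixime,0.5,AF
C008,Cefixime,0.5,AF
C009,Cefixime,0.5,AF
C010,Cefixime,0.5,AF
C011,Cefixime,0.5,AF
C012,Cefixime,0.5,AF
C013,Cefixime,0.5,AF
C014,Cefixime,0.5,AF
C015,Cefixime,0.5,AF
C016,Cefixime,0.5,AF
C017,Cefixime,0.5,AF
C018,Cefixime,0.5,AF
C019,Cefixime,0.5,AF
C020,Cefixime,0.5,AF
C021,Cefixime,0.5,RE
C022,Cefixime,0.5,RE
C023,Cefixime,0.5,RE
C024,Cefixime,0.5,RE
C025,Cefixime,0.5,RE
C026,Cefixime,0.5,RE
C027,Cefixime,1.0,censor
C028,Cefixime,1.0,censor
C029,Cefixime,1.0,censor
C030,Cefixime,1.0,censor
C031,Cefixime,1.0,censor
C032,Cefixime,1.0,censor
C033,Cefixime,1.0,censor
C034,Cefixime,1.0,censor
C035,Cefixime,1.0,censor
C036,Cefixime,1.0,censor
C037,Cefixime,1.0,censor
C038,Cefixime,1.0,censor
C039,Cefixime,1.0,censor
C040,Cefixime,1.0,censor
C041,Cefixime,1.0,censor
C042,Cefixime,1.0,censor
C043,Cefixime,1.0,censor
C044,Cefixime,1.0,censor
C045,Cefixime,1.0,censor
C046,Cefixime,1.0,censor
C047,Cefixime,1.0,censor
C048,Cefixime,1.0,censor
C049,Cefixime,1.0,censor
C050,Cefixime,1.0,censor
C051,Cefixime,1.0,censor
C052,Cefixime,1.0,censor
C053,Cefixime,1.0,censor
C054,Cefixime,1.0,censor
C055,Cefixime,1.0,censor
C056,Cefixime,1.0,censor
C057,Cefixime,1.0,censor
C058,Cefixime,1.0,censor
C059,Cefixime,1.0,censor
C060,Cefixime,1.0,censor
C061,Cefixime,1.0,censor
C062,Cefixime,1.0,censor
C063,Cefixime,1.0,censor
C064,Cefixime,1.0,censor
C065,Cefixime,1.0,censor
C066,Cefixime,1.0,censor
C067,Cefixime,1.0,censor
C068,Cefixime,1.0,censor
C069,Cefixime,1.0,censor
C070,Cefixime,1.0,censor
C071,Cefixime,1.0,censor
C072,Cefixime,1.0,censor
C073,Cefixime,1.0,censor
C074,Cefixime,1.0,censor
C075,Cefixime,1.0,censor
C076,Cefixime,1.0,censor
C077,Cefixime,1.0,censor
G001,Gatifloxacin,0.5,AF
G002,Gatifloxacin,0.5,RE
G003,Gatifloxacin,0.5,RE
G004,Gatifloxacin,1.0,censor
G005,Gatifloxacin,1.0,censor
G006,Gatifloxacin,1.0,censor
G007,Gatifloxacin,1.0,censor
G008,Gatifloxacin,1.0,censor
G009,Gatifloxacin,1.0,censor
G010,Gatifloxacin,1.0,censor
G011,Gatifloxacin,1.0,censor
G012,Gatifloxacin,1.0,censor
G013,Gatifloxacin,1.0,censor
G014,Gatifloxacin,1.0,censor
G015,Gatifloxacin,1.0,censor
G016,Gatifloxacin,1.0,censor
G017,Gatifloxacin,1.0,censor
G018,Gatifloxacin,1.0,censor
G019,Gatifloxacin,1.0,censor
G020,Gatifloxacin,1.0,censor
G021,Gatifloxacin,1.0,censor
G022,Gatifloxacin,1.0,censor
G023,Gatifloxacin,1.0,censor
G024,Gatifloxacin,1.0,censor
G025,Gatifloxacin,1.0,censor
G026,Gatifloxacin,1.0,censor
G027,Gatifloxacin,1.0,censor
G028,Gatifloxacin,1.0,censor
G029,Gatifloxacin,1.0,censor
G030,Gatifloxacin,1.0,censor
G031,Gatifloxacin,1.0,censor
G032,Gatifloxacin,1.0,censor
G033,Gatifloxacin,1.0,censor
G034,Gatifloxacin,1.0,censor
G035,Gatifloxacin,1.0,censor
G036,Gatifloxacin,1.0,censor
G037,Gatifloxacin,1.0,censor
G038,Gatifloxacin,1.0,censor
G039,Gatifloxacin,1.0,censor
G040,Gatifloxacin,1.0,censor
G041,Gatifloxacin,1.0,censor
G042,Gatifloxacin,1.0,censor
G043,Gatifloxacin,1.0,censor
G044,Gatifloxacin,1.0,censor
G045,Gatifloxacin,1.0,censor
G046,Gatifloxacin,1.0,censor
G047,Gatifloxacin,1.0,censor
G048,Gatifloxacin,1.0,censor
G049,Gatifloxacin,1.0,censor
G050,Gatifloxacin,1.0,censor
G051,Gatifloxacin,1.0,censor
G052,Gatifloxacin,1.0,censor
G053,Gatifloxacin,1.0,censor
G054,Gatifloxacin,1.0,censor
G055,Gatifloxacin,1.0,censor
G056,Gatifloxacin,1.0,censor
G057,Gatifloxacin,1.0,censor
G058,Gatifloxacin,1.0,censor
G059,Gatifloxacin,1.0,censor
G060,Gatifloxacin,1.0,censor
G061,Gatifloxacin,1.0,censor
G062,Gatifloxacin,1.0,censor
G063,Gatifloxacin,1.0,censor
G064,Gatifloxacin,1.0,censor
G065,Gatifloxacin,1.0,censor
G066,Gatifloxacin,1.0,censor
G067,Gatifloxacin,1.0,censor
G068,Gatifloxacin,1.0,censor
G069,Gatifloxacin,1.0,censor
G070,Gatifloxacin,1.0,censor
G071,Gatifloxacin,1.0,censor
G072,Gatifloxacin,1.0,censor
G073,Gatifloxacin,1.0,censor
G074,Gatifloxacin,1.0,censor
G075,Gatifloxacin,1.0,censor
G076,Gatifloxacin,1.0,censor
G077,Gatifloxacin,1.0,censor
G078,Gatifloxacin,1.0,censor
G079,Gatifloxacin,1.0,censor
G080,Gatifloxacin,1.0,censor
G081,Gatifloxacin,1.0,censor
G082,Gatifloxacin,1.0,censor
G083,Gatifloxacin,1.0,censor
G084,Gatifloxacin,1.0,censor
G085,Gatifloxacin,1.0,censor
G086,Gatifloxacin,1.0,censor
G087,Gatifloxacin,1.0,censor
G088,Gatifloxacin,1.0,censor
G089,Gatifloxacin,1.0,censor
G090,Gatifloxacin,1.0,censor
G091,Gatifloxacin,1.0,censor
G092,Gatifloxacin,1.0,censor
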