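id,sire,dam,sex,natal_pack,birth_year
I,0,0,M,0,0
II,0,0,F,0,0
III,0,0,M,0,0
IV,0,0,M,0,0
V,0,0,M,0,0
VI,0,0,M,0,0
VII,0,0,M,0,0
VIII,0,0,M,0,0
IX,0,0,F,0,0
X,0,0,F,0,0
XI,0,0,M,0,0
XII,0,0,F,0,0
XIII,0,0,F,0,0
GW023f,0,0,F,0,0
GW064m,0,0,M,0,0
GW001m,0,0,M,0,0
GW042m,0,0,M,0,0
GW104m,0,0,M,0,0
GW105m,0,0,M,0,0
GW106m,0,0,M,0,0
GW096m,0,0,M,0,0
GW123m,0,0,M,0,0
GW144m,0,0,M,0,0
GW153m,0,0,M,0,0
GW161m,0,0,M,0,0
GW187m,0,0,M,0,0
GW207m,0,0,M,0,0
GW237m,0,0,M,0,0
GW243m,0,0,M,0,0
GW246m,0,0,M,0,0
GW249m,0,0,M,0,0
GW260m,0,0,M,0,0
GW294m,0,0,M,0,0
GW295m,0,0,M,0,0
GW301m,0,0,M,0,0
GW362m,0,0,M,0,0
GW381m,0,0,M,0,0
GW411m,0,0,M,0,0
GW417m,0,0,M,0,0
GW586m,0,0,M,0,0
GW589m,0,0,M,0,0
GW239f,0,0,F,0,0
GW245f,0,0,F,0,0
GW258f,0,0,F,0,0
GW262f,0,0,F,0,0
GW340f,0,0,F,0,0
GW342f,0,0,F,0,0
GW552f,0,0,F,0,0
GW006f,I,GW023f,F,MH,2000
GW008m,I,GW023f,M,MH,2001
GW012f,GW064m,GW023f,F,MH,2002
GW131f,GW064m,GW023f,F,MH,2004
GW016f,GW001m,GW006f,F,N,2005
GW024f,GW001m,GW006f,F,N,2005
GW026f,GW001m,GW006f,F,N,2005
GW007f,GW001m,GW006f,F,N,2006
GW130f,GW001m,GW006f,F,N,2007
GW132f,GW001m,GW006f,F,N,2008
GW223m,GW001m,GW006f,M,N,2008
GW194m,GW187m,GW016f,M,AG,2010
GW195f,GW187m,GW016f,F,AG,2010
GW188m,GW187m,GW016f,M,AG,2011
GW191f,GW187m,GW016f,F,AG,2011
GW208m,GW187m,GW016f,M,AG,2011
GW185f,GW187m,GW016f,F,AG,2009
GW186m,GW187m,GW016f,M,AG,2011
GW196f,GW187m,GW016f,F,AG,2010
GW202f,GW187m,GW016f,F,AG,2011
GW203f,GW187m,GW016f,F,AG,2012
GW227f,GW187m,GW016f,F,AG,2012
GW348f,GW187m,GW016f,F,AG,2013
GW025m,GW008m,GW012f,M,NO,2006
GW038m,GW008m,GW012f,M,NO,2006
GW037m,GW008m,GW012f,M,NO,2008
GW068m,GW008m,GW012f,M,NO,2010
GW071f,GW008m,GW012f,F,NO,2010
GW087f,GW008m,GW012f,F,NO,2010
GW097m,GW008m,GW012f,M,NO,2010
GW214f,GW008m,GW012f,F,NO,2010
GW014m,GW042m,II,M,DZ,2006
GW031f,GW042m,II,F,DZ,2008
GW541f,GW105m,GW087f,F,DZ,2012
GW213m,GW014m,GW006f,M,SL,2009
GW070m,GW014m,GW006f,M,SL,2009
GW056f,GW014m,GW006f,F,SL,2009
GW067f,GW014m,GW006f,F,SL,2010
GW085f,GW014m,GW006f,F,SL,2010
GW050f,GW025m,GW026f,F,MI,2008
GW058f,GW025m,GW026f,F,MI,2008
GW112f,GW042m,GW026f,F,MI,2011
GW287m,GW042m,GW026f,M,MI,2011
GW180f,GW014m,GW026f,F,MI,2013
GW114f,GW038m,GW024f,F,DN,2008
GW116f,GW038m,GW024f,F,DN,2010
GW215m,GW038m,GW024f,M,DN,2010
GW178f,GW038m,GW024f,F,DN,2011
GW288m,VI,GW114f,M,DN,2012
GW177f,VI,GW114f,F,DN,2012
GW128m,GW123m,GW007f,M,WE,2009
GW139f,GW123m,GW007f,F,WE,2009
GW140f,GW123m,GW007f,F,WE,2010
GW347f,GW070m,GW139f,F,WE,2012
GW111m,GW104m,GW056f,M,KH,2011
GW293f,GW104m,GW056f,F,KH,2012
GW404m,GW104m,GW056f,M,KH,2012
GW149m,GW207m,GW140f,M,SPJ,2012
GW250m,GW207m,GW140f,M,SPJ,2012
GW349m,GW207m,GW140f,M,SPJ,2013
GW351f,GW207m,GW140f,F,SPJ,2013
GW218m,GW161m,GW185f,M,LE,2011
GW242f,GW161m,GW185f,F,LE,2011
GW163f,GW161m,GW185f,F,LE,2013
GW233m,GW237m,GW196f,M,GKL,2012
GW257f,GW237m,GW196f,F,GKL,2012
GW323f,GW237m,GW196f,F,GKL,2013
GW333m,GW237m,GW196f,M,GKL,2013
GW263f,GW213m,GW214f,F,MU,2012
GW339m,GW213m,GW214f,M,MU,2013
GW283m,GW037m,GW058f,M,SP,2012
GW277f,GW037m,GW058f,F,SP,2012
GW566m,GW037m,GW058f,M,SP,2013
GW098f,GW037m,GW058f,F,SP,2011
GW169f,GW037m,GW058f,F,SP,2011
GW367m,GW188m,GW191f,M,BE,2013
GW306f,GW111m,GW245f,F,GR,2013
GW497f,GW208m,GW340f,F,CLH,2013
GW599m,GW294m,GW112f,M,RT,2014
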