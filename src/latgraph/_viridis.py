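"""The 256-entry viridis colormap table (sRGB, rows = r, g, b in [0, 1]).

Embedded so that colour assignment is bit-stable and carries no plotting
dependency at runtime.
"""

import numpy as np

VIRIDIS_TABLE = np.array([
    [np.float64(0.267004), np.float64(0.004874), np.float64(0.329415)],
    [np.float64(0.26851), np.float64(0.009605), np.float64(0.335427)],
    [np.float64(0.269944), np.float64(0.014625), np.float64(0.341379)],
    [np.float64(0.271305), np.float64(0.019942), np.float64(0.347269)],
    [np.float64(0.272594), np.float64(0.025563), np.float64(0.353093)],
    [np.float64(0.273809), np.float64(0.031497), np.float64(0.358853)],
    [np.float64(0.274952), np.float64(0.037752), np.float64(0.364543)],
    [np.float64(0.276022), np.float64(0.044167), np.float64(0.370164)],
    [np.float64(0.277018), np.float64(0.050344), np.float64(0.375715)],
    [np.float64(0.277941), np.float64(0.056324), np.float64(0.381191)],
    [np.float64(0.278791), np.float64(0.062145), np.float64(0.386592)],
    [np.float64(0.279566), np.float64(0.067836), np.float64(0.391917)],
    [np.float64(0.280267), np.float64(0.073417), np.float64(0.397163)],
    [np.float64(0.280894), np.float64(0.078907), np.float64(0.402329)],
    [np.float64(0.281446), np.float64(0.08432), np.float64(0.407414)],
    [np.float64(0.281924), np.float64(0.089666), np.float64(0.412415)],
    [np.float64(0.282327), np.float64(0.094955), np.float64(0.417331)],
    [np.float64(0.282656), np.float64(0.100196), np.float64(0.42216)],
    [np.float64(0.28291), np.float64(0.105393), np.float64(0.426902)],
    [np.float64(0.283091), np.float64(0.110553), np.float64(0.431554)],
    [np.float64(0.283197), np.float64(0.11568), np.float64(0.436115)],
    [np.float64(0.283229), np.float64(0.120777), np.float64(0.440584)],
    [np.float64(0.283187), np.float64(0.125848), np.float64(0.44496)],
    [np.float64(0.283072), np.float64(0.130895), np.float64(0.449241)],
    [np.float64(0.282884), np.float64(0.13592), np.float64(0.453427)],
    [np.float64(0.282623), np.float64(0.140926), np.float64(0.457517)],
    [np.float64(0.28229), np.float64(0.145912), np.float64(0.46151)],
    [np.float64(0.281887), np.float64(0.150881), np.float64(0.465405)],
    [np.float64(0.281412), np.float64(0.155834), np.float64(0.469201)],
    [np.float64(0.280868), np.float64(0.160771), np.float64(0.472899)],
    [np.float64(0.280255), np.float64(0.165693), np.float64(0.476498)],
    [np.float64(0.279574), np.float64(0.170599), np.float64(0.479997)],
    [np.float64(0.278826), np.float64(0.17549), np.float64(0.483397)],
    [np.float64(0.278012), np.float64(0.180367), np.float64(0.486697)],
    [np.float64(0.277134), np.float64(0.185228), np.float64(0.489898)],
    [np.float64(0.276194), np.float64(0.190074), np.float64(0.493001)],
    [np.float64(0.275191), np.float64(0.194905), np.float64(0.496005)],
    [np.float64(0.274128), np.float64(0.199721), np.float64(0.498911)],
    [np.float64(0.273006), np.float64(0.20452), np.float64(0.501721)],
    [np.float64(0.271828), np.float64(0.209303), np.float64(0.504434)],
    [np.float64(0.270595), np.float64(0.214069), np.float64(0.507052)],
    [np.float64(0.269308), np.float64(0.218818), np.float64(0.509577)],
    [np.float64(0.267968), np.float64(0.223549), np.float64(0.512008)],
    [np.float64(0.26658), np.float64(0.228262), np.float64(0.514349)],
    [np.float64(0.265145), np.float64(0.232956), np.float64(0.516599)],
    [np.float64(0.263663), np.float64(0.237631), np.float64(0.518762)],
    [np.float64(0.262138), np.float64(0.242286), np.float64(0.520837)],
    [np.float64(0.260571), np.float64(0.246922), np.float64(0.522828)],
    [np.float64(0.258965), np.float64(0.251537), np.float64(0.524736)],
    [np.float64(0.257322), np.float64(0.25613), np.float64(0.526563)],
    [np.float64(0.255645), np.float64(0.260703), np.float64(0.528312)],
    [np.float64(0.253935), np.float64(0.265254), np.float64(0.529983)],
    [np.float64(0.252194), np.float64(0.269783), np.float64(0.531579)],
    [np.float64(0.250425), np.float64(0.27429), np.float64(0.533103)],
    [np.float64(0.248629), np.float64(0.278775), np.float64(0.534556)],
    [np.float64(0.246811), np.float64(0.283237), np.float64(0.535941)],
    [np.float64(0.244972), np.float64(0.287675), np.float64(0.53726)],
    [np.float64(0.243113), np.float64(0.292092), np.float64(0.538516)],
    [np.float64(0.241237), np.float64(0.296485), np.float64(0.539709)],
    [np.float64(0.239346), np.float64(0.300855), np.float64(0.540844)],
    [np.float64(0.237441), np.float64(0.305202), np.float64(0.541921)],
    [np.float64(0.235526), np.float64(0.309527), np.float64(0.542944)],
    [np.float64(0.233603), np.float64(0.313828), np.float64(0.543914)],
    [np.float64(0.231674), np.float64(0.318106), np.float64(0.544834)],
    [np.float64(0.229739), np.float64(0.322361), np.float64(0.545706)],
    [np.float64(0.227802), np.float64(0.326594), np.float64(0.546532)],
    [np.float64(0.225863), np.float64(0.330805), np.float64(0.547314)],
    [np.float64(0.223925), np.float64(0.334994), np.float64(0.548053)],
    [np.float64(0.221989), np.float64(0.339161), np.float64(0.548752)],
    [np.float64(0.220057), np.float64(0.343307), np.float64(0.549413)],
    [np.float64(0.21813), np.float64(0.347432), np.float64(0.550038)],
    [np.float64(0.21621), np.float64(0.351535), np.float64(0.550627)],
    [np.float64(0.214298), np.float64(0.355619), np.float64(0.551184)],
    [np.float64(0.212395), np.float64(0.359683), np.float64(0.55171)],
    [np.float64(0.210503), np.float64(0.363727), np.float64(0.552206)],
    [np.float64(0.208623), np.float64(0.367752), np.float64(0.552675)],
    [np.float64(0.206756), np.float64(0.371758), np.float64(0.553117)],
    [np.float64(0.204903), np.float64(0.375746), np.float64(0.553533)],
    [np.float64(0.203063), np.float64(0.379716), np.float64(0.553925)],
    [np.float64(0.201239), np.float64(0.38367), np.float64(0.554294)],
    [np.float64(0.19943), np.float64(0.387607), np.float64(0.554642)],
    [np.float64(0.197636), np.float64(0.391528), np.float64(0.554969)],
    [np.float64(0.19586), np.float64(0.395433), np.float64(0.555276)],
    [np.float64(0.1941), np.float64(0.399323), np.float64(0.555565)],
    [np.float64(0.192357), np.float64(0.403199), np.float64(0.555836)],
    [np.float64(0.190631), np.float64(0.407061), np.float64(0.556089)],
    [np.float64(0.188923), np.float64(0.41091), np.float64(0.556326)],
    [np.float64(0.187231), np.float64(0.414746), np.float64(0.556547)],
    [np.float64(0.185556), np.float64(0.41857), np.float64(0.556753)],
    [np.float64(0.183898), np.float64(0.422383), np.float64(0.556944)],
    [np.float64(0.182256), np.float64(0.426184), np.float64(0.55712)],
    [np.float64(0.180629), np.float64(0.429975), np.float64(0.557282)],
    [np.float64(0.179019), np.float64(0.433756), np.float64(0.55743)],
    [np.float64(0.177423), np.float64(0.437527), np.float64(0.557565)],
    [np.float64(0.175841), np.float64(0.44129), np.float64(0.557685)],
    [np.float64(0.174274), np.float64(0.445044), np.float64(0.557792)],
    [np.float64(0.172719), np.float64(0.448791), np.float64(0.557885)],
    [np.float64(0.171176), np.float64(0.45253), np.float64(0.557965)],
    [np.float64(0.169646), np.float64(0.456262), np.float64(0.55803)],
    [np.float64(0.168126), np.float64(0.459988), np.float64(0.558082)],
    [np.float64(0.166617), np.float64(0.463708), np.float64(0.558119)],
    [np.float64(0.165117), np.float64(0.467423), np.float64(0.558141)],
    [np.float64(0.163625), np.float64(0.471133), np.float64(0.558148)],
    [np.float64(0.162142), np.float64(0.474838), np.float64(0.55814)],
    [np.float64(0.160665), np.float64(0.47854), np.float64(0.558115)],
    [np.float64(0.159194), np.float64(0.482237), np.float64(0.558073)],
    [np.float64(0.157729), np.float64(0.485932), np.float64(0.558013)],
    [np.float64(0.15627), np.float64(0.489624), np.float64(0.557936)],
    [np.float64(0.154815), np.float64(0.493313), np.float64(0.55784)],
    [np.float64(0.153364), np.float64(0.497), np.float64(0.557724)],
    [np.float64(0.151918), np.float64(0.500685), np.float64(0.557587)],
    [np.float64(0.150476), np.float64(0.504369), np.float64(0.55743)],
    [np.float64(0.149039), np.float64(0.508051), np.float64(0.55725)],
    [np.float64(0.147607), np.float64(0.511733), np.float64(0.557049)],
    [np.float64(0.14618), np.float64(0.515413), np.float64(0.556823)],
    [np.float64(0.144759), np.float64(0.519093), np.float64(0.556572)],
    [np.float64(0.143343), np.float64(0.522773), np.float64(0.556295)],
    [np.float64(0.141935), np.float64(0.526453), np.float64(0.555991)],
    [np.float64(0.140536), np.float64(0.530132), np.float64(0.555659)],
    [np.float64(0.139147), np.float64(0.533812), np.float64(0.555298)],
    [np.float64(0.13777), np.float64(0.537492), np.float64(0.554906)],
    [np.float64(0.136408), np.float64(0.541173), np.float64(0.554483)],
    [np.float64(0.135066), np.float64(0.544853), np.float64(0.554029)],
    [np.float64(0.133743), np.float64(0.548535), np.float64(0.553541)],
    [np.float64(0.132444), np.float64(0.552216), np.float64(0.553018)],
    [np.float64(0.131172), np.float64(0.555899), np.float64(0.552459)],
    [np.float64(0.129933), np.float64(0.559582), np.float64(0.551864)],
    [np.float64(0.128729), np.float64(0.563265), np.float64(0.551229)],
    [np.float64(0.127568), np.float64(0.566949), np.float64(0.550556)],
    [np.float64(0.126453), np.float64(0.570633), np.float64(0.549841)],
    [np.float64(0.125394), np.float64(0.574318), np.float64(0.549086)],
    [np.float64(0.124395), np.float64(0.578002), np.float64(0.548287)],
    [np.float64(0.123463), np.float64(0.581687), np.float64(0.547445)],
    [np.float64(0.122606), np.float64(0.585371), np.float64(0.546557)],
    [np.float64(0.121831), np.float64(0.589055), np.float64(0.545623)],
    [np.float64(0.121148), np.float64(0.592739), np.float64(0.544641)],
    [np.float64(0.120565), np.float64(0.596422), np.float64(0.543611)],
    [np.float64(0.120092), np.float64(0.600104), np.float64(0.54253)],
    [np.float64(0.119738), np.float64(0.603785), np.float64(0.5414)],
    [np.float64(0.119512), np.float64(0.607464), np.float64(0.540218)],
    [np.float64(0.119423), np.float64(0.611141), np.float64(0.538982)],
    [np.float64(0.119483), np.float64(0.614817), np.float64(0.537692)],
    [np.float64(0.119699), np.float64(0.61849), np.float64(0.536347)],
    [np.float64(0.120081), np.float64(0.622161), np.float64(0.534946)],
    [np.float64(0.120638), np.float64(0.625828), np.float64(0.533488)],
    [np.float64(0.12138), np.float64(0.629492), np.float64(0.531973)],
    [np.float64(0.122312), np.float64(0.633153), np.float64(0.530398)],
    [np.float64(0.123444), np.float64(0.636809), np.float64(0.528763)],
    [np.float64(0.12478), np.float64(0.640461), np.float64(0.527068)],
    [np.float64(0.126326), np.float64(0.644107), np.float64(0.525311)],
    [np.float64(0.128087), np.float64(0.647749), np.float64(0.523491)],
    [np.float64(0.130067), np.float64(0.651384), np.float64(0.521608)],
    [np.float64(0.132268), np.float64(0.655014), np.float64(0.519661)],
    [np.float64(0.134692), np.float64(0.658636), np.float64(0.517649)],
    [np.float64(0.137339), np.float64(0.662252), np.float64(0.515571)],
    [np.float64(0.14021), np.float64(0.665859), np.float64(0.513427)],
    [np.float64(0.143303), np.float64(0.669459), np.float64(0.511215)],
    [np.float64(0.146616), np.float64(0.67305), np.float64(0.508936)],
    [np.float64(0.150148), np.float64(0.676631), np.float64(0.506589)],
    [np.float64(0.153894), np.float64(0.680203), np.float64(0.504172)],
    [np.float64(0.157851), np.float64(0.683765), np.float64(0.501686)],
    [np.float64(0.162016), np.float64(0.687316), np.float64(0.499129)],
    [np.float64(0.166383), np.float64(0.690856), np.float64(0.496502)],
    [np.float64(0.170948), np.float64(0.694384), np.float64(0.493803)],
    [np.float64(0.175707), np.float64(0.6979), np.float64(0.491033)],
    [np.float64(0.180653), np.float64(0.701402), np.float64(0.488189)],
    [np.float64(0.185783), np.float64(0.704891), np.float64(0.485273)],
    [np.float64(0.19109), np.float64(0.708366), np.float64(0.482284)],
    [np.float64(0.196571), np.float64(0.711827), np.float64(0.479221)],
    [np.float64(0.202219), np.float64(0.715272), np.float64(0.476084)],
    [np.float64(0.20803), np.float64(0.718701), np.float64(0.472873)],
    [np.float64(0.214), np.float64(0.722114), np.float64(0.469588)],
    [np.float64(0.220124), np.float64(0.725509), np.float64(0.466226)],
    [np.float64(0.226397), np.float64(0.728888), np.float64(0.462789)],
    [np.float64(0.232815), np.float64(0.732247), np.float64(0.459277)],
    [np.float64(0.239374), np.float64(0.735588), np.float64(0.455688)],
    [np.float64(0.24607), np.float64(0.73891), np.float64(0.452024)],
    [np.float64(0.252899), np.float64(0.742211), np.float64(0.448284)],
    [np.float64(0.259857), np.float64(0.745492), np.float64(0.444467)],
    [np.float64(0.266941), np.float64(0.748751), np.float64(0.440573)],
    [np.float64(0.274149), np.float64(0.751988), np.float64(0.436601)],
    [np.float64(0.281477), np.float64(0.755203), np.float64(0.432552)],
    [np.float64(0.288921), np.float64(0.758394), np.float64(0.428426)],
    [np.float64(0.296479), np.float64(0.761561), np.float64(0.424223)],
    [np.float64(0.304148), np.float64(0.764704), np.float64(0.419943)],
    [np.float64(0.311925), np.float64(0.767822), np.float64(0.415586)],
    [np.float64(0.319809), np.float64(0.770914), np.float64(0.411152)],
    [np.float64(0.327796), np.float64(0.77398), np.float64(0.40664)],
    [np.float64(0.335885), np.float64(0.777018), np.float64(0.402049)],
    [np.float64(0.344074), np.float64(0.780029), np.float64(0.397381)],
    [np.float64(0.35236), np.float64(0.783011), np.float64(0.392636)],
    [np.float64(0.360741), np.float64(0.785964), np.float64(0.387814)],
    [np.float64(0.369214), np.float64(0.788888), np.float64(0.382914)],
    [np.float64(0.377779), np.float64(0.791781), np.float64(0.377939)],
    [np.float64(0.386433), np.float64(0.794644), np.float64(0.372886)],
    [np.float64(0.395174), np.float64(0.797475), np.float64(0.367757)],
    [np.float64(0.404001), np.float64(0.800275), np.float64(0.362552)],
    [np.float64(0.412913), np.float64(0.803041), np.float64(0.357269)],
    [np.float64(0.421908), np.float64(0.805774), np.float64(0.35191)],
    [np.float64(0.430983), np.float64(0.808473), np.float64(0.346476)],
    [np.float64(0.440137), np.float64(0.811138), np.float64(0.340967)],
    [np.float64(0.449368), np.float64(0.813768), np.float64(0.335384)],
    [np.float64(0.458674), np.float64(0.816363), np.float64(0.329727)],
    [np.float64(0.468053), np.float64(0.818921), np.float64(0.323998)],
    [np.float64(0.477504), np.float64(0.821444), np.float64(0.318195)],
    [np.float64(0.487026), np.float64(0.823929), np.float64(0.312321)],
    [np.float64(0.496615), np.float64(0.826376), np.float64(0.306377)],
    [np.float64(0.506271), np.float64(0.828786), np.float64(0.300362)],
    [np.float64(0.515992), np.float64(0.831158), np.float64(0.294279)],
    [np.float64(0.525776), np.float64(0.833491), np.float64(0.288127)],
    [np.float64(0.535621), np.float64(0.835785), np.float64(0.281908)],
    [np.float64(0.545524), np.float64(0.838039), np.float64(0.275626)],
    [np.float64(0.555484), np.float64(0.840254), np.float64(0.269281)],
    [np.float64(0.565498), np.float64(0.84243), np.float64(0.262877)],
    [np.float64(0.575563), np.float64(0.844566), np.float64(0.256415)],
    [np.float64(0.585678), np.float64(0.846661), np.float64(0.249897)],
    [np.float64(0.595839), np.float64(0.848717), np.float64(0.243329)],
    [np.float64(0.606045), np.float64(0.850733), np.float64(0.236712)],
    [np.float64(0.616293), np.float64(0.852709), np.float64(0.230052)],
    [np.float64(0.626579), np.float64(0.854645), np.float64(0.223353)],
    [np.float64(0.636902), np.float64(0.856542), np.float64(0.21662)],
    [np.float64(0.647257), np.float64(0.8584), np.float64(0.209861)],
    [np.float64(0.657642), np.float64(0.860219), np.float64(0.203082)],
    [np.float64(0.668054), np.float64(0.861999), np.float64(0.196293)],
    [np.float64(0.678489), np.float64(0.863742), np.float64(0.189503)],
    [np.float64(0.688944), np.float64(0.865448), np.float64(0.182725)],
    [np.float64(0.699415), np.float64(0.867117), np.float64(0.175971)],
    [np.float64(0.709898), np.float64(0.868751), np.float64(0.169257)],
    [np.float64(0.720391), np.float64(0.87035), np.float64(0.162603)],
    [np.float64(0.730889), np.float64(0.871916), np.float64(0.156029)],
    [np.float64(0.741388), np.float64(0.873449), np.float64(0.149561)],
    [np.float64(0.751884), np.float64(0.874951), np.float64(0.143228)],
    [np.float64(0.762373), np.float64(0.876424), np.float64(0.137064)],
    [np.float64(0.772852), np.float64(0.877868), np.float64(0.131109)],
    [np.float64(0.783315), np.float64(0.879285), np.float64(0.125405)],
    [np.float64(0.79376), np.float64(0.880678), np.float64(0.120005)],
    [np.float64(0.804182), np.float64(0.882046), np.float64(0.114965)],
    [np.float64(0.814576), np.float64(0.883393), np.float64(0.110347)],
    [np.float64(0.82494), np.float64(0.88472), np.float64(0.106217)],
    [np.float64(0.83527), np.float64(0.886029), np.float64(0.102646)],
    [np.float64(0.845561), np.float64(0.887322), np.float64(0.099702)],
    [np.float64(0.85581), np.float64(0.888601), np.float64(0.097452)],
    [np.float64(0.866013), np.float64(0.889868), np.float64(0.095953)],
    [np.float64(0.876168), np.float64(0.891125), np.float64(0.09525)],
    [np.float64(0.886271), np.float64(0.892374), np.float64(0.095374)],
    [np.float64(0.89632), np.float64(0.893616), np.float64(0.096335)],
    [np.float64(0.906311), np.float64(0.894855), np.float64(0.098125)],
    [np.float64(0.916242), np.float64(0.896091), np.float64(0.100717)],
    [np.float64(0.926106), np.float64(0.89733), np.float64(0.104071)],
    [np.float64(0.935904), np.float64(0.89857), np.float64(0.108131)],
    [np.float64(0.945636), np.float64(0.899815), np.float64(0.112838)],
    [np.float64(0.9553), np.float64(0.901065), np.float64(0.118128)],
    [np.float64(0.964894), np.float64(0.902323), np.float64(0.123941)],
    [np.float64(0.974417), np.float64(0.90359), np.float64(0.130215)],
    [np.float64(0.983868), np.float64(0.904867), np.float64(0.136897)],
    [np.float64(0.993248), np.float64(0.906157), np.float64(0.143936)],
])
VIRIDIS_TABLE.setflags(write=False)
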